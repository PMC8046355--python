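"""Binomial test of in-frame fusion-read enrichment under selection.

Fusion reads span the prey-vector junction and reveal the reading frame of
the prey insert. Under random three-frame cloning about one third of fusion
reads are in frame; a prey whose in-frame proportion rises under selection
is being selected *because* its translated product interacts with the bait.

For prey k with bait i, in-frame counts Y_c out of F_c fusion reads in
condition c in {S, N} are modeled Binomial(F_c, pi_c) and the one-sided
hypothesis pi_N < pi_S is tested with the pooled two-proportion Z statistic

    rho = (pi_S - pi_N) / sqrt( pi (1 - pi) (1/F_S + 1/F_N) ),

with pi the pooled proportion. Counts are aggregated across replicates
within condition before testing.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, FusionTable

#: sentinel magnitude for a zero pooled variance with unequal proportions
LARGE_RHO = 1e6

#: in-frame proportion of a random three-frame cloning library
NULL_INFRAME = 1.0 / 3.0


@dataclasses.dataclass
class InframeStat:
    """Z statistic for in-frame enrichment of one (bait, prey) pair."""

    bait: str
    prey: str
    pi_S: float  # observed in-frame proportion, selected (NaN if f_S = 0)
    pi_N: float
    pi_pooled: float
    rho: float  # NaN when undefined (no fusion reads in a condition)
    f_S: int
    f_N: int
    sentinel: bool = False  # True when rho was clamped to +-LARGE_RHO


def inframe_z(
    y_S: int, f_S: int, y_N: int, f_N: int, bait: str = "", prey: str = ""
) -> InframeStat:
    """Pooled two-proportion Z statistic of in-frame enrichment.

    Returns a missing (NaN) statistic when either condition has no fusion
    reads; a zero pooled variance with unequal proportions is clamped to the
    +-LARGE_RHO sentinel (only the rank of rho matters downstream).
    """
    if not (0 <= y_S <= f_S and 0 <= y_N <= f_N):
        raise ValueError("need 0 <= y <= f in both conditions")
    if f_S == 0 or f_N == 0:
        return InframeStat(
            bait, prey,
            pi_S=math.nan if f_S == 0 else y_S / f_S,
            pi_N=math.nan if f_N == 0 else y_N / f_N,
            pi_pooled=math.nan, rho=math.nan, f_S=f_S, f_N=f_N,
        )
    pi_S = y_S / f_S
    pi_N = y_N / f_N
    pooled = (y_S + y_N) / (f_S + f_N)
    var = pooled * (1.0 - pooled) * (1.0 / f_S + 1.0 / f_N)
    if var == 0.0:
        if pi_S == pi_N:
            rho, sentinel = 0.0, False
        else:
            rho, sentinel = math.copysign(LARGE_RHO, pi_S - pi_N), True
    else:
        rho, sentinel = (pi_S - pi_N) / math.sqrt(var), False
    return InframeStat(bait, prey, pi_S, pi_N, pooled, rho, f_S, f_N, sentinel)


def inframe_z_default_null(
    y_S: int,
    f_S: int,
    pi_N: float = NULL_INFRAME,
    f_N_effective: int | None = None,
    bait: str = "",
    prey: str = "",
) -> InframeStat:
    """Z statistic when non-selected fusion data are unavailable.

    Substitutes the random-cloning null proportion (pi_N = 1/3 by default)
    with an effective non-selected depth; by default the null pseudo-sample
    is as deep as the selected one (f_N_effective = f_S).
    """
    if f_S == 0:
        return InframeStat(bait, prey, math.nan, pi_N, math.nan, math.nan, 0, 0)
    f_N = f_S if f_N_effective is None else f_N_effective
    y_N = pi_N * f_N
    pi_S = y_S / f_S
    pooled = (y_S + y_N) / (f_S + f_N)
    var = pooled * (1.0 - pooled) * (1.0 / f_S + 1.0 / f_N)
    if var == 0.0:
        if pi_S == pi_N:
            rho, sentinel = 0.0, False
        else:
            rho, sentinel = math.copysign(LARGE_RHO, pi_S - pi_N), True
    else:
        rho, sentinel = (pi_S - pi_N) / math.sqrt(var), False
    return InframeStat(bait, prey, pi_S, pi_N, pooled, rho, f_S, int(f_N), sentinel)


def inframe_stats(
    fusion: FusionTable,
    counts: CountMatrix,
    assume_null_third: bool = False,
) -> pd.DataFrame:
    """Per-(bait, prey) in-frame Z statistics from a fusion-read table.

    Replicates are pooled within condition. With ``assume_null_third`` the
    non-selected data are ignored and the 1/3 default null is used (for
    designs without non-selected controls).
    """
    agg = fusion.aggregate(counts)
    wide = agg.pivot_table(
        index=["bait", "prey"],
        columns="condition",
        values=["inframe_reads", "fusion_reads"],
        fill_value=0,
    )
    rows = []
    for (bait, prey), r in wide.iterrows():
        y_S = int(r[("inframe_reads", "selected")])
        f_S = int(r[("fusion_reads", "selected")])
        if assume_null_third:
            st = inframe_z_default_null(y_S, f_S, bait=bait, prey=prey)
        else:
            y_N = int(r[("inframe_reads", "non_selected")])
            f_N = int(r[("fusion_reads", "non_selected")])
            st = inframe_z(y_S, f_S, y_N, f_N, bait=bait, prey=prey)
        rows.append(st)
    out = pd.DataFrame([dataclasses.asdict(s) for s in rows])
    return out.sort_values(["bait", "prey"], ignore_index=True)


def _vectorized_rho(
    y_S: np.ndarray, f_S: np.ndarray, y_N: np.ndarray, f_N: np.ndarray
) -> np.ndarray:
    """Array version of :func:`inframe_z`; NaN where either depth is zero."""
    y_S, f_S = np.asarray(y_S, float), np.asarray(f_S, float)
    y_N, f_N = np.asarray(y_N, float), np.asarray(f_N, float)
    rho = np.full(y_S.shape, np.nan)
    ok = (f_S > 0) & (f_N > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_S = y_S / f_S
        pi_N = y_N / f_N
        pooled = (y_S + y_N) / (f_S + f_N)
        var = pooled * (1 - pooled) * (1 / f_S + 1 / f_N)
        raw = (pi_S - pi_N) / np.sqrt(var)
    degen = ok & (var == 0)
    rho[ok] = raw[ok]
    rho[degen & (pi_S == pi_N)] = 0.0
    uneq = degen & (pi_S != pi_N)
    rho[uneq] = np.sign((pi_S - pi_N)[uneq]) * LARGE_RHO
    return rho


def inframe_stats_fast(fusion: FusionTable, counts: CountMatrix) -> pd.DataFrame:
    """Vectorized replicate-pooled rho per (bait, prey); same contract as
    :func:`inframe_stats` without the per-pair dataclasses (used on large
    simulated screens)."""
    agg = fusion.aggregate(counts)
    wide = agg.pivot_table(
        index=["bait", "prey"],
        columns="condition",
        values=["inframe_reads", "fusion_reads"],
        fill_value=0,
    )
    rho = _vectorized_rho(
        wide[("inframe_reads", "selected")].to_numpy(),
        wide[("fusion_reads", "selected")].to_numpy(),
        wide[("inframe_reads", "non_selected")].to_numpy(),
        wide[("fusion_reads", "non_selected")].to_numpy(),
    )
    out = wide.index.to_frame(index=False)
    out["rho"] = rho
    out["f_S"] = wide[("fusion_reads", "selected")].to_numpy()
    out["f_N"] = wide[("fusion_reads", "non_selected")].to_numpy()
    return out.sort_values(["bait", "prey"], ignore_index=True)
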