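"""Differential-enrichment contrasts of prey counts.

Two families of negative-binomial Wald contrasts feed the scores:

* enrichment — for each bait, selected vs. non-selected replicates; the
  non-selected condition is the negative control for reporter-independent
  library abundance;
* specificity — for each ordered pair of baits, selected vs. selected; the
  other baits act as controls for promiscuous (sticky / auto-active) preys.

Raw integer counts plus size-factor offsets enter the NB model; pre-divided
normalized matrices are rounded back to integers (with a warning) since the
NB likelihood needs counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, SampleMeta
from .nbglm import nb_wald_two_group
from .normalization import median_of_ratios_factors


def compute_size_factors(cm: CountMatrix, method: str = "library_size") -> np.ndarray:
    """Per-sample size factors, normalized to geometric mean 1.

    ``library_size`` scales by column totals; ``median_of_ratios`` uses the
    replicate-group median-of-ratios estimator.
    """
    if method == "library_size":
        totals = cm.values().astype(float).sum(axis=0)
        if (totals <= 0).any():
            bad = cm.sample_ids[int(np.argmax(totals <= 0))]
            raise ValueError(f"sample {bad!r} has zero total count")
        sf = totals
    elif method == "median_of_ratios":
        sf = median_of_ratios_factors(cm)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    return sf / np.exp(np.mean(np.log(sf)))


def _integer_counts(cm: CountMatrix) -> np.ndarray:
    arr = cm.values()
    if cm.normalized_by != "none" and not np.allclose(arr, np.round(arr)):
        warnings.warn(
            "normalized (non-integer) counts supplied; rounding to nearest "
            "integer for the NB model — prefer raw counts plus size factors",
            stacklevel=3,
        )
        arr = np.round(arr)
    return np.asarray(arr, dtype=np.int64)


def fit_enrichment(
    cm: CountMatrix,
    bait: str,
    size_factors: np.ndarray | None = None,
    size_factor_method: str = "library_size",
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """NB Wald contrast of selected over non-selected for one bait.

    Returns one row per prey: bait, prey, log2fc, pvalue, base_mean,
    dispersion. All-zero preys get log2fc 0 and missing p.
    """
    if bait not in cm.baits:
        raise ValueError(f"bait {bait!r} not present in sample metadata")
    sel = cm.sample_index(bait=bait, condition="selected")
    non = cm.sample_index(bait=bait, condition="non_selected")
    if len(sel) == 0 or len(non) == 0:
        raise ValueError(f"bait {bait!r} lacks samples in one condition")
    if size_factors is None:
        size_factors = compute_size_factors(cm, size_factor_method)
    idx = np.concatenate([non, sel])
    counts = _integer_counts(cm)[:, idx]
    fit = nb_wald_two_group(
        counts,
        size_factors[idx],
        is_treatment=np.concatenate(
            [np.zeros(len(non), bool), np.ones(len(sel), bool)]
        ),
        lfc_threshold=lfc_threshold,
    )
    return pd.DataFrame(
        {
            "bait": bait,
            "prey": cm.preys,
            "log2fc": fit.log2fc,
            "pvalue": fit.pvalue,
            "base_mean": fit.base_mean,
            "dispersion": fit.dispersion,
        }
    )


def fit_all_enrichment(
    cm: CountMatrix,
    size_factors: np.ndarray | None = None,
    size_factor_method: str = "library_size",
) -> pd.DataFrame:
    if size_factors is None:
        size_factors = compute_size_factors(cm, size_factor_method)
    return pd.concat(
        [fit_enrichment(cm, b, size_factors) for b in cm.baits], ignore_index=True
    )


def fit_specificity_pairs(
    cm: CountMatrix,
    baits: list[str] | None = None,
    size_factors: np.ndarray | None = None,
    size_factor_method: str = "library_size",
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """NB Wald contrasts between all ordered pairs of selected baits.

    One row per (bait_i, bait_j, prey) for i != j; fold-changes are
    antisymmetric (the (j, i) rows mirror the (i, j) fit with flipped sign
    and identical p-values).
    """
    if baits is None:
        baits = cm.baits
    if len(baits) < 2:
        raise ValueError("specificity contrasts need at least 2 baits")
    if size_factors is None:
        size_factors = compute_size_factors(cm, size_factor_method)
    frames = []
    for a_pos, bi in enumerate(baits):
        sel_i = cm.sample_index(bait=bi, condition="selected")
        for bj in baits[a_pos + 1 :]:
            sel_j = cm.sample_index(bait=bj, condition="selected")
            idx = np.concatenate([sel_j, sel_i])
            counts = _integer_counts(cm)[:, idx]
            fit = nb_wald_two_group(
                counts,
                size_factors[idx],
                is_treatment=np.concatenate(
                    [np.zeros(len(sel_j), bool), np.ones(len(sel_i), bool)]
                ),
                lfc_threshold=lfc_threshold,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "bait": bi,
                        "bait_other": bj,
                        "prey": cm.preys,
                        "log2fc": fit.log2fc,
                        "pvalue": fit.pvalue,
                        "base_mean": fit.base_mean,
                        "dispersion": fit.dispersion,
                    }
                )
            )
            frames.append(
                pd.DataFrame(
                    {
                        "bait": bj,
                        "bait_other": bi,
                        "prey": cm.preys,
                        "log2fc": -fit.log2fc,
                        "pvalue": fit.pvalue,
                        "base_mean": fit.base_mean,
                        "dispersion": fit.dispersion,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def make_pseudo_replicates(cm: CountMatrix) -> CountMatrix:
    """Duplicate singleton (bait, condition) samples so NB fits are possible.

    The duplicated sample is flagged ``pseudo`` in the metadata; downstream
    dispersion estimates for such groups sit at the moderation floor since
    the duplicates carry no replicate variation.
    """
    new_cols: list[pd.Series] = []
    new_meta: list[SampleMeta] = []
    for (bait, cond), idx in cm.replicate_groups().items():
        for i in idx:
            new_cols.append(cm.counts.iloc[:, i])
            new_meta.append(cm.samples[i])
        if len(idx) == 1:
            src = cm.samples[idx[0]]
            dup_id = f"{src.sample_id}_pseudo"
            col = cm.counts.iloc[:, idx[0]].rename(dup_id)
            new_cols.append(col)
            new_meta.append(
                SampleMeta(
                    sample_id=dup_id,
                    bait=bait,
                    condition=cond,
                    replicate=src.replicate + 1,
                    pseudo=True,
                )
            )
    df = pd.concat(new_cols, axis=1)
    return CountMatrix(df, new_meta, normalized_by=cm.normalized_by)
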