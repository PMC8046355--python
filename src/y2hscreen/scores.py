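"""Rank-based interaction scores and their Borda ensemble.

Three scores, each in [0, 1], grade every (bait, prey) pair:

* enrichment — ranks of log2 fold-change nested within ranks of p-values
  from the selected vs. non-selected contrast;
* specificity — the same rank-within-rank construction on the pairwise
  selected-bait contrasts, averaged over the other baits, with a hard zero
  for preys depleted (f < 0) or non-significant against a given bait;
* in-frame — the rank of the in-frame Z statistic among all pairs.

The rank-within-rank construction: pairs with p <= alpha form the candidate
set; the p-value component is (N - R(p)) / N with ascending competition
ranks; the candidate set is cut into b = alpha / w p-value windows and
fold-changes are ranked (descending) within their window, scaled by the
window's p-score spread so the fold-change can only refine, never overturn,
the p-value ordering. The combined score is rescaled by its global maximum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclasses.dataclass
class ScoreParams:
    """Thresholds and window layout for the enrichment/specificity scores.

    ``alpha`` (``*_p_val``) excludes pairs with larger p from the candidate
    set; ``*_fold_change`` zeroes the score of any pair whose log2
    fold-change falls below the threshold (default 0: depleted preys score
    zero — only enrichment in the right direction supports an interaction);
    ``n_windows`` is b = alpha / w. If ``window_width`` is given it is
    adjusted downward so that it divides alpha exactly.
    """

    enrich_p_val: float = 1.0
    enrich_fold_change: float = 0.0
    spec_p_val: float = 1.0
    spec_fold_change: float = 0.0
    n_windows: int = 10
    window_width: float | None = None

    def __post_init__(self) -> None:
        for a in (self.enrich_p_val, self.spec_p_val):
            if not (0 < a <= 1):
                raise ValueError("p-value thresholds must lie in (0, 1]")
        if self.window_width is not None:
            if not (0 < self.window_width <= min(self.enrich_p_val, self.spec_p_val)):
                raise ValueError("window width must lie in (0, alpha]")
            self.n_windows = int(np.ceil(self.enrich_p_val / self.window_width))
        if self.n_windows < 1:
            raise ValueError("need at least one p-value window")

    def width(self, alpha: float) -> float:
        return alpha / self.n_windows


def _window_index(p: np.ndarray, alpha: float, b: int) -> np.ndarray:
    """Window 1..b for each p: window l covers ((l-1)w, lw], p = 0 -> 1."""
    w = alpha / b
    return np.clip(np.ceil(p / w).astype(int), 1, b)


def _rank_within_rank(
    p: np.ndarray, f: np.ndarray, alpha: float, b: int, zero: np.ndarray | None = None
) -> np.ndarray:
    """Combined p-then-fold-change score for members of the candidate set.

    ``zero`` optionally forces individual members' p-components to zero
    (the specificity f < 0 rule) before windows are combined.
    """
    member = p <= alpha
    out = np.zeros(len(p))
    n = int(member.sum())
    if n == 0:
        return out
    pm = p[member]
    fm = f[member]
    rank_p = rankdata(pm, method="min")
    score_p = (n - rank_p) / n
    if zero is not None:
        score_p = np.where(zero[member], 0.0, score_p)
    win = _window_index(pm, alpha, b)
    combined = score_p.copy()
    for l in np.unique(win):
        sel = win == l
        rank_f = rankdata(-fm[sel], method="min")
        max_r = rank_f.max()
        score_f = (max_r - rank_f) / max_r
        if zero is not None:
            score_f = np.where(zero[member][sel], 0.0, score_f)
        spread = (score_p[sel].max() - score_p[sel].min()) / sel.sum()
        combined[sel] = score_p[sel] + spread * score_f
    out[member] = combined
    return out


def enrichment_score(results: pd.DataFrame, params: ScoreParams | None = None) -> pd.DataFrame:
    """Enrichment score per (bait, prey) from selected vs. non-selected fits.

    Missing p-values count as 1, missing fold-changes as 0; pairs with
    p > alpha score zero. The result carries one row per input row with an
    ``enrichment`` column in [0, 1].
    """
    params = params or ScoreParams()
    if results.empty:
        return results.assign(enrichment=pd.Series(dtype=float))[
            ["bait", "prey", "enrichment"]
        ]
    p = results["pvalue"].fillna(1.0).to_numpy(dtype=float)
    f = results["log2fc"].fillna(0.0).to_numpy(dtype=float)
    raw = _rank_within_rank(
        p, f, params.enrich_p_val, params.n_windows,
        zero=(f < params.enrich_fold_change),
    )
    m = raw.max()
    if m > 0:
        raw = raw / m
    return pd.DataFrame(
        {"bait": results["bait"], "prey": results["prey"], "enrichment": raw}
    )


def specificity_score(
    pairwise: pd.DataFrame, params: ScoreParams | None = None, n_baits: int | None = None
) -> pd.DataFrame:
    """Specificity score per (bait, prey) from pairwise selected-bait fits.

    Each ordered triple (i, j, k) contributes a rank-within-rank score that
    is hard-zeroed when f_ijk < 0 or p_ijk > alpha; triples are averaged
    over the n_b - 1 comparison baits j and rescaled globally.
    """
    params = params or ScoreParams()
    baits = pd.unique(pairwise["bait"]) if n_baits is None else None
    n_b = len(baits) if n_baits is None else n_baits
    if n_b < 2:
        raise ValueError("specificity score needs at least 2 baits")
    p = pairwise["pvalue"].fillna(1.0).to_numpy(dtype=float)
    f = pairwise["log2fc"].fillna(0.0).to_numpy(dtype=float)
    combined = _rank_within_rank(
        p, f, params.spec_p_val, params.n_windows,
        zero=(f < params.spec_fold_change),
    )
    per_pair = (
        pd.DataFrame(
            {"bait": pairwise["bait"], "prey": pairwise["prey"], "s": combined}
        )
        .groupby(["bait", "prey"], as_index=False, sort=True)["s"]
        .sum()
    )
    per_pair["s"] = per_pair["s"] / (n_b - 1)
    m = per_pair["s"].max()
    if m > 0:
        per_pair["s"] = per_pair["s"] / m
    return per_pair.rename(columns={"s": "specificity"})


def inframe_score(stats: pd.DataFrame) -> pd.DataFrame:
    """In-frame score: ascending rank of rho over defined pairs, scaled so
    the largest rho maps to 1; pairs without fusion reads score zero."""
    rho = stats["rho"].to_numpy(dtype=float)
    out = np.zeros(len(rho))
    defined = ~np.isnan(rho)
    if defined.any():
        r = rankdata(rho[defined], method="min")
        out[defined] = r / r.max()
    return pd.DataFrame(
        {"bait": stats["bait"], "prey": stats["prey"], "inframe": out}
    )


def borda_ensemble(
    scores: pd.DataFrame,
    which: tuple[str, ...] = ("enrichment", "specificity", "inframe"),
) -> pd.Series:
    """Classic Borda (mean-rank) aggregation of the component scores.

    Ranks are ascending (largest score gets the largest rank, mid-rank for
    ties), averaged across the available components within each bait and
    rescaled to [0, 1] by the maximum mean rank of that bait.
    """
    if not which:
        raise ValueError("need at least one component score")
    out = np.zeros(len(scores))
    for _, idx in scores.groupby("bait").groups.items():
        sub = scores.loc[idx]
        ranks = np.column_stack(
            [rankdata(sub[c].to_numpy(), method="average") for c in which]
        )
        mean_rank = ranks.mean(axis=1)
        out[scores.index.get_indexer(idx)] = mean_rank / mean_rank.max()
    return pd.Series(out, index=scores.index, name="borda")


def compute_score_table(
    enrich_results: pd.DataFrame | None,
    pairwise_results: pd.DataFrame | None,
    inframe_df: pd.DataFrame | None,
    params: ScoreParams | None = None,
) -> pd.DataFrame:
    """Assemble the full score table from whichever model outputs exist.

    Absent inputs yield a zero column for that score and the Borda ensemble
    aggregates only the available components.
    """
    params = params or ScoreParams()
    parts: list[pd.DataFrame] = []
    available: list[str] = []
    if enrich_results is not None and not enrich_results.empty:
        parts.append(enrichment_score(enrich_results, params).set_index(["bait", "prey"]))
        available.append("enrichment")
    if pairwise_results is not None and not pairwise_results.empty:
        parts.append(
            specificity_score(pairwise_results, params).set_index(["bait", "prey"])
        )
        available.append("specificity")
    if inframe_df is not None and not inframe_df.empty:
        parts.append(inframe_score(inframe_df).set_index(["bait", "prey"]))
        available.append("inframe")
    if not parts:
        raise ValueError("no model outputs supplied")
    table = pd.concat(parts, axis=1).fillna(0.0).reset_index()
    for col in ("enrichment", "specificity", "inframe"):
        if col not in table.columns:
            table[col] = 0.0
    table = table.sort_values(["bait", "prey"], ignore_index=True)
    table["borda"] = borda_ensemble(table, tuple(available))
    return table[["bait", "prey", "enrichment", "specificity", "inframe", "borda"]]
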