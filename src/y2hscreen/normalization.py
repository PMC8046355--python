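"""Count normalization methods and replicate-agreement diagnostics.

Four normalizations are provided: counts-per-million library-size scaling,
transcripts per million (TPM), median-of-ratios size factors (computed per
bait x condition replicate group), and removal of unwanted variation using
replicate samples (RUVs, k factors of within-replicate-group variation
removed on the log scale).

Diagnostics mirror how screen replicate quality is usually assessed: the
per-prey coefficient of variation across replicates, pairwise Pearson
correlations between samples of a condition, and paired Wilcoxon
signed-rank comparisons of CV distributions between methods.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CountMatrix

SCALE = 1e6  # counts-per-million convention


def normalize_library_size(cm: CountMatrix) -> CountMatrix:
    """Scale each sample to a constant total of 1e6 (CPM)."""
    arr = cm.values().astype(float)
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = cm.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    out = pd.DataFrame(
        arr * (SCALE / totals), index=cm.counts.index, columns=cm.counts.columns
    )
    return cm.with_counts(out, "library_size")


def normalize_tpm(cm: CountMatrix, lengths: pd.Series) -> CountMatrix:
    """Transcripts per million given per-prey fragment lengths in bases."""
    missing = [p for p in cm.preys if p not in lengths.index]
    if missing:
        raise ValueError(f"missing lengths for preys: {missing[:5]}")
    L = lengths.reindex(cm.preys).to_numpy(dtype=float)
    if (L <= 0).any():
        raise ValueError("prey lengths must be positive")
    rate = cm.values().astype(float) / L[:, None]
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = cm.sample_ids[int(np.argmax(denom == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    out = pd.DataFrame(
        rate * (SCALE / denom), index=cm.counts.index, columns=cm.counts.columns
    )
    return cm.with_counts(out, "tpm")


def median_of_ratios_factors(
    cm: CountMatrix, groups: list[list[int]] | None = None
) -> np.ndarray:
    """Per-sample size factors via the median-of-ratios estimator.

    Geometric means are taken over preys with strictly positive counts in
    every sample of the group; each sample's factor is the median ratio of
    its counts to those geometric means.
    """
    arr = cm.values().astype(float)
    if groups is None:
        groups = list(cm.replicate_groups().values())
    factors = np.full(arr.shape[1], np.nan)
    for idx in groups:
        sub = arr[:, idx]
        pos = (sub > 0).all(axis=1)
        if not pos.any():
            raise ValueError(
                f"no prey has positive counts in all samples of group {idx}"
            )
        loggeo = np.log(sub[pos]).mean(axis=1)
        for j, col in enumerate(idx):
            factors[col] = np.exp(np.median(np.log(sub[pos, j]) - loggeo))
    if np.isnan(factors).any():
        raise ValueError("sample grouping does not cover all samples")
    return factors


def normalize_median_of_ratios(
    cm: CountMatrix, groups: list[list[int]] | None = None
) -> CountMatrix:
    factors = median_of_ratios_factors(cm, groups)
    out = pd.DataFrame(
        cm.values().astype(float) / factors,
        index=cm.counts.index,
        columns=cm.counts.columns,
    )
    return cm.with_counts(out, "median_of_ratios")


def normalize_ruvs(
    cm: CountMatrix,
    replicate_groups: list[list[int]] | None = None,
    k: int = 1,
) -> CountMatrix:
    """Remove k factors of unwanted within-replicate-group variation.

    Works on log(x+1) counts: samples are centered within their replicate
    group, the centered matrix is decomposed by SVD, and the leading k
    sample-space directions are regressed out of the full log matrix. The
    replicate-sample variant needs no negative-control genes; all preys act
    as controls.

    Default grouping follows screen practice: selected samples grouped by
    bait, all non-selected samples in one group.
    """
    if replicate_groups is None:
        rg = cm.replicate_groups()
        replicate_groups = [
            idx for (bait, cond), idx in rg.items() if cond == "selected"
        ]
        nonsel = [i for i, s in enumerate(cm.samples) if s.condition == "non_selected"]
        if nonsel:
            replicate_groups.append(nonsel)
    if k == 0:
        return cm.with_counts(cm.counts.astype(float), "ruvs")
    for g in replicate_groups:
        if len(g) < 2:
            raise ValueError(f"replicate group {g} has fewer than 2 samples")
    n_samples = len(cm.samples)
    if k >= n_samples:
        raise ValueError(f"k = {k} must be smaller than the number of samples")

    logx = np.log1p(cm.values().astype(float)).T  # samples x preys
    resid = np.zeros_like(logx)
    for g in replicate_groups:
        g = np.asarray(g)
        resid[g] = logx[g] - logx[g].mean(axis=0, keepdims=True)
    # leading directions of replicate disagreement
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    w = u[:, :k] * s[:k]  # unwanted factor loadings per sample
    alpha = vt[:k]  # per-prey coefficients
    clean = logx - w @ alpha
    out = np.clip(np.expm1(clean), 0.0, None).T
    out_df = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    # zeros stay zeros: log1p(0)=0 rows never gain mass from centered residuals
    out_df[cm.counts == 0] = 0.0
    return cm.with_counts(out_df, "ruvs")


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def prey_cv(cm: CountMatrix) -> pd.DataFrame:
    """Coefficient of variation per prey within each (bait, condition) group.

    CV = sd / mean over replicates (ddof=1); preys with zero mean in a group
    are reported as NaN.
    """
    rows = []
    arr = cm.values().astype(float)
    for (bait, cond), idx in cm.replicate_groups().items():
        if len(idx) < 2:
            raise ValueError(f"group ({bait}, {cond}) has fewer than 2 replicates")
        sub = arr[:, idx]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
        rows.append(
            pd.DataFrame(
                {"bait": bait, "condition": cond, "prey": cm.preys, "cv": cv}
            )
        )
    return pd.concat(rows, ignore_index=True)


def pairwise_pearson(cm: CountMatrix, condition: str) -> pd.DataFrame:
    """Pearson correlation between all pairs of samples of one condition."""
    idx = cm.sample_index(condition=condition)
    if len(idx) < 2:
        raise ValueError(f"fewer than 2 samples in condition {condition!r}")
    sub = cm.values().astype(float)[:, idx]
    ids = [cm.sample_ids[i] for i in idx]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub.T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)


def wilcoxon_paired(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Paired Wilcoxon signed-rank p-value; exact for n <= 25 pairs.

    Larger samples use the normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    diffs = a - b
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0
    method = "exact" if len(diffs) <= 25 else "approx"
    res = stats.wilcoxon(
        diffs, alternative=alternative, method=method, correction=(method == "approx")
    )
    return float(res.pvalue)


@dataclasses.dataclass
class NormalizationReport:
    """Replicate-agreement diagnostics for a set of normalization methods."""

    cv: pd.DataFrame  # method, bait, condition, prey, cv
    pearson: pd.DataFrame  # method, condition, sample_a, sample_b, r
    cv_wilcoxon: pd.DataFrame  # method_a, method_b, pvalue (paired, two-sided)


def build_report(normalized: dict[str, CountMatrix]) -> NormalizationReport:
    cv_frames, cor_frames = [], []
    for method, cm in normalized.items():
        c = prey_cv(cm)
        c.insert(0, "method", method)
        cv_frames.append(c)
        for cond in ("selected", "non_selected"):
            if len(cm.sample_index(condition=cond)) >= 2:
                corr = pairwise_pearson(cm, cond)
                ids = list(corr.index)
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        cor_frames.append(
                            {
                                "method": method,
                                "condition": cond,
                                "sample_a": ids[i],
                                "sample_b": ids[j],
                                "r": corr.iloc[i, j],
                            }
                        )
    cv_all = pd.concat(cv_frames, ignore_index=True)
    tests = []
    methods = list(normalized)
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            a = cv_all[cv_all["method"] == ma].sort_values(
                ["bait", "condition", "prey"]
            )["cv"].to_numpy()
            b = cv_all[cv_all["method"] == mb].sort_values(
                ["bait", "condition", "prey"]
            )["cv"].to_numpy()
            tests.append(
                {"method_a": ma, "method_b": mb, "pvalue": wilcoxon_paired(a, b)}
            )
    return NormalizationReport(
        cv=cv_all,
        pearson=pd.DataFrame(cor_frames),
        cv_wilcoxon=pd.DataFrame(tests),
    )


def pca_projection(cm: CountMatrix, n_components: int = 2) -> pd.DataFrame:
    """Centered, unscaled PCA of log2(x+1) counts; samples as rows. Plumbing."""
    from sklearn.decomposition import PCA

    x = np.log2(cm.values().astype(float) + 1).T
    proj = PCA(n_components=n_components).fit_transform(x - x.mean(axis=0))
    return pd.DataFrame(
        proj,
        index=cm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(proj.shape[1])],
    )
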