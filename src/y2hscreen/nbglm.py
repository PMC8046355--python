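"""Vectorized gene-wise negative binomial Wald tests for two-group contrasts.

Counts for one prey (gene) in samples r are modeled as
``Z_r ~ NB(mean = s_r * m_{g(r)}, dispersion = alpha)`` where ``s_r`` is a
size factor, ``g(r)`` the sample's group and ``alpha`` the gene's
overdispersion (variance = mu + alpha * mu^2). The fitting scheme follows
the standard RNA-seq playbook:

1. gene-wise dispersion by alternating maximum likelihood (Newton in
   log-alpha, group means profiled out),
2. a parametric mean-dispersion trend ``alpha(mu) = a0 + a1 / mu``,
3. empirical-Bayes moderation of the gene-wise estimate toward the trend
   (normal prior on log dispersion, prior width estimated from the spread
   of the gene-wise estimates around the trend),
4. a Wald test of the group contrast at the moderated dispersion, with
   fitted means floored at 0.5 so that all-zero groups stay informative.

Everything is vectorized across genes; a contrast over 20,000 preys and six
samples fits in well under a second.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special, stats

MIN_DISP = 1e-8
MAX_DISP = 30.0
MIN_MU = 0.5  # floor on fitted means, keeps all-zero groups testable


@dataclasses.dataclass
class NBFit:
    """Result of a two-group NB Wald contrast, arrays over genes."""

    log2fc: np.ndarray  # group A over group B
    pvalue: np.ndarray  # two-sided Wald; NaN for all-zero genes
    base_mean: np.ndarray  # mean of size-factor-scaled counts
    dispersion: np.ndarray  # moderated dispersion estimate
    se_log2fc: np.ndarray


def _fit_group_means(
    z: np.ndarray, sf: np.ndarray, groups: np.ndarray, alpha: np.ndarray, n_iter: int = 7
) -> np.ndarray:
    """Profile MLE of per-group means m_g given dispersion, Newton in log m.

    Returns array (genes, n_groups). Score in eta=log m is
    sum_r (z - mu) / (1 + alpha mu); information sum_r mu / (1 + alpha mu).
    """
    n_groups = groups.max() + 1
    means = np.empty((z.shape[0], n_groups))
    for g in range(n_groups):
        cols = groups == g
        zg = z[:, cols]
        sg = sf[cols]
        m = np.maximum((zg / sg).mean(axis=1), MIN_MU / 2)
        eta = np.log(m)
        a = alpha[:, None]
        for _ in range(n_iter):
            mu = np.maximum(np.exp(eta)[:, None] * sg, MIN_MU)
            denom = 1.0 + a * mu
            score = ((zg - mu) / denom).sum(axis=1)
            info = (mu / denom).sum(axis=1)
            step = np.clip(score / np.maximum(info, 1e-12), -3.0, 3.0)
            eta = eta + step
        means[:, g] = np.exp(eta)
    return means


def _dloglik_dlogalpha(
    z: np.ndarray, mu: np.ndarray, log_alpha: np.ndarray
) -> np.ndarray:
    """d/d(log alpha) of the NB log-likelihood summed over samples."""
    alpha = np.exp(log_alpha)[:, None]
    k = 1.0 / alpha  # size parameter
    term = (
        special.digamma(z + k)
        - special.digamma(k)
        + np.log(k / (k + mu))
        + 1.0
        - (z + k) / (k + mu)
    ).sum(axis=1)
    # dl/dk * dk/dlog(alpha) = dl/dk * (-k)
    return -term * k[:, 0]


def _cox_reid_grad(
    mu: np.ndarray, log_alpha: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """d/d(log alpha) of the Cox-Reid adjustment -0.5 log det(X'WX).

    For the two-group design the determinant factorizes over groups, with
    W = mu / (1 + alpha mu); the adjustment removes the small-sample bias
    of the profile dispersion estimate.
    """
    alpha = np.exp(log_alpha)[:, None]
    denom = 1.0 + alpha * mu
    dw = alpha * mu**2 / denom**2  # -dw/dlog(alpha)
    w = mu / denom
    out = np.zeros(mu.shape[0])
    for g in np.unique(groups):
        cols = groups == g
        out += 0.5 * dw[:, cols].sum(axis=1) / np.maximum(w[:, cols].sum(axis=1), 1e-12)
    return out


def _newton_log_alpha(
    z: np.ndarray,
    sf: np.ndarray,
    groups: np.ndarray,
    log_alpha0: np.ndarray,
    prior_mean: np.ndarray | None = None,
    prior_var: float = np.inf,
    n_outer: int = 2,
    n_inner: int = 6,
) -> np.ndarray:
    """Maximize the Cox-Reid adjusted (penalized) profile likelihood in
    log alpha, vectorized over genes.

    With a finite ``prior_var`` this is the MAP estimate under a normal
    prior on log dispersion centered at ``prior_mean``.
    """
    log_alpha = log_alpha0.copy()
    lo, hi = np.log(MIN_DISP), np.log(MAX_DISP)
    h = 1e-2

    def grad(la: np.ndarray, mu: np.ndarray) -> np.ndarray:
        g = _dloglik_dlogalpha(z, mu, la) + _cox_reid_grad(mu, la, groups)
        if prior_mean is not None and np.isfinite(prior_var):
            g = g - (la - prior_mean) / prior_var
        return g

    for _ in range(n_outer):
        means = _fit_group_means(z, sf, groups, np.exp(log_alpha))
        mu = np.maximum(means[:, groups] * sf, MIN_MU)
        for _ in range(n_inner):
            # gradient and curvature from one symmetric evaluation pair
            gp = grad(log_alpha + h, mu)
            gm = grad(log_alpha - h, mu)
            g = 0.5 * (gp + gm)
            hess = (gp - gm) / (2 * h)
            step = np.where(hess < -1e-10, -g / hess, np.sign(g) * 0.5)
            log_alpha = np.clip(log_alpha + np.clip(step, -2.0, 2.0), lo, hi)
    return log_alpha


def _moments_dispersion(z: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Method-of-moments start: (pooled within-group var - mean) / mean^2."""
    y = z / sf
    n_groups = groups.max() + 1
    ss = np.zeros(z.shape[0])
    dof = 0
    for g in range(n_groups):
        cols = groups == g
        yg = y[:, cols]
        ss += ((yg - yg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += cols.sum() - 1
    var = ss / max(dof, 1)
    mean = np.maximum(y.mean(axis=1), 1e-8)
    xim = np.mean(1.0 / sf)
    return np.clip((var - xim * mean) / mean**2, MIN_DISP, MAX_DISP)


def _fit_trend(base_mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Parametric trend alpha(mu) = a0 + a1/mu fit by iterated NNLS."""
    use = (disp > MIN_DISP * 10) & (base_mean > 0)
    if use.sum() < 10:
        med = float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01
        return max(med, 1e-6), 0.0
    mu = base_mean[use]
    a = disp[use]
    for _ in range(4):
        design = np.column_stack([np.ones_like(mu), 1.0 / mu])
        coef, _ = optimize.nnls(design, a)
        fit = design @ coef
        ratio = a / np.maximum(fit, 1e-12)
        keep = (ratio < 15) & (ratio > 1e-4)
        if keep.all() or keep.sum() < 10:
            break
        mu, a = mu[keep], a[keep]
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 <= 0 and a1 <= 0:
        a0 = 1e-6
    return a0, a1


def nb_wald_two_group(
    counts: np.ndarray,
    size_factors: np.ndarray,
    is_treatment: np.ndarray,
    lfc_threshold: float = 0.0,
) -> NBFit:
    """Two-group NB Wald contrast (treatment over reference) per gene.

    Parameters
    ----------
    counts : (genes, samples) non-negative integer array.
    size_factors : (samples,) positive scale factors (offsets).
    is_treatment : (samples,) boolean; True marks the numerator group.
    lfc_threshold : composite null |log2fc| <= threshold; 0 gives the plain
        Wald test.
    """
    z = np.asarray(counts, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    treat = np.asarray(is_treatment, dtype=bool)
    if z.shape[1] != len(sf) or len(sf) != len(treat):
        raise ValueError("counts, size_factors and is_treatment disagree in length")
    if treat.all() or not treat.any():
        raise ValueError("both groups must contain at least one sample")
    if treat.sum() < 2 or (~treat).sum() < 2:
        raise ValueError("each group needs >= 2 replicates (use pseudo-replicates)")

    n_genes, m = z.shape
    groups = treat.astype(int)  # 0 = reference, 1 = treatment
    base_mean = (z / sf).mean(axis=1)
    nonzero = z.sum(axis=1) > 0

    log2fc = np.zeros(n_genes)
    pvalue = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    dispersion = np.full(n_genes, np.nan)

    if nonzero.any():
        zz = z[nonzero]
        # 1. gene-wise MLE dispersion
        la0 = np.log(_moments_dispersion(zz, sf, groups))
        la_mle = _newton_log_alpha(zz, sf, groups, la0)
        # 2. mean-dispersion trend
        a0, a1 = _fit_trend(base_mean[nonzero], np.exp(la_mle))
        la_trend = np.log(
            np.clip(a0 + a1 / np.maximum(base_mean[nonzero], 1e-8), MIN_DISP, MAX_DISP)
        )
        # 3. prior width from robust spread of gene-wise around trend
        resid = la_mle - la_trend
        informative = la_mle > np.log(MIN_DISP * 10)
        if informative.sum() >= 10:
            s_lr = stats.median_abs_deviation(resid[informative], scale="normal")
        else:
            s_lr = 0.5
        var_samp = special.polygamma(1, max(m - 2, 1) / 2.0)
        prior_var = max(s_lr**2 - var_samp, 0.25)
        # 4. MAP dispersion and Wald test
        la_map = _newton_log_alpha(
            zz, sf, groups, la_mle, prior_mean=la_trend, prior_var=prior_var
        )
        alpha = np.exp(la_map)
        means = _fit_group_means(zz, sf, groups, alpha)
        means = np.maximum(means, MIN_MU)
        mu = np.maximum(means[:, groups] * sf, MIN_MU)
        w = mu / (1.0 + alpha[:, None] * mu)
        var_eta = 1.0 / w[:, groups == 1].sum(axis=1) + 1.0 / w[:, groups == 0].sum(
            axis=1
        )
        l2fc = np.log2(means[:, 1] / means[:, 0])
        se_l2 = np.sqrt(var_eta) / np.log(2.0)
        zstat = (np.abs(l2fc) - lfc_threshold) / se_l2
        p = 2.0 * stats.norm.sf(np.maximum(zstat, 0.0))
        p = np.minimum(p, 1.0)

        log2fc[nonzero] = l2fc
        pvalue[nonzero] = p
        se[nonzero] = se_l2
        dispersion[nonzero] = alpha

    return NBFit(
        log2fc=log2fc,
        pvalue=pvalue,
        base_mean=base_mean,
        dispersion=dispersion,
        se_log2fc=se,
    )
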