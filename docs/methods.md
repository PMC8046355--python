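# Methods

`y2hscreen` ranks candidate protein–protein interactions from batch-culture
yeast two-hybrid screens read out by deep sequencing (Y2H-NGIS). A diploid
population carrying one bait and a cDNA prey library is split into a
non-selected culture (plasmid maintenance only) and a selected culture
(reporter activation required for growth); prey cDNA is amplified and
sequenced from both at saturation. The package computes three
complementary, rank-based scores per (bait, prey) pair, a Borda ensemble,
and provides a generative simulator with known truth labels for end-to-end
validation.

## Statistical models

### Negative binomial differential enrichment

Prey read counts are modeled per prey (gene) as

    Z_r ~ NB(mean = s_r · m_g(r), dispersion = α),
    Var(Z) = μ + α μ²,

with per-sample size factors `s_r` entering as offsets and a two-level
group mean (selected vs. non-selected for the *enrichment* contrast; bait i
vs. bait j, both selected, for the *specificity* contrasts). Fitting
follows the standard RNA-seq playbook, vectorized across all preys:

1. gene-wise dispersion by Cox–Reid–adjusted profile maximum likelihood
   (Newton in log α, group means profiled out; the CR adjustment
   `−½ log det(XᵀWX)` removes the small-sample downward bias);
2. a parametric mean–dispersion trend `α(μ) = a₀ + a₁/μ` fit by iterated
   non-negative least squares with outlier exclusion;
3. empirical-Bayes moderation: a normal prior on log α centered on the
   trend, prior variance estimated from the robust spread of the gene-wise
   estimates minus the sampling variance `ψ₁((m−p)/2)`, floored at 0.25;
4. a Wald test of the group contrast at the moderated (MAP) dispersion.
   Fitted means are floored at 0.5 so a condition with all-zero counts
   still yields a finite, strongly significant contrast rather than an
   infinite standard error.

Dispersions are bounded to [1e−8, 30]. With 3+3 replicates and 2,000 null
preys at shared dispersion 0.1 the p-value distribution is uniform to
KS < 0.03 and the type-I error at nominal 0.05 is ≈ 0.05–0.06; a planted
8-fold enrichment is recovered with median log2 fold-change ≈ 3.0 (the
test suite checks all three properties, plus rank agreement with an
independent NB engine on a shared fixture).

Counts must be raw integers; size factors (library-size totals or
median-of-ratios, geometric-mean-normalized) carry the normalization. A
supplied pre-normalized matrix is rounded back to integers with a warning.
Designs without biological replicates can duplicate singleton samples
(`make_pseudo_replicates`); the duplicated group contributes no replicate
variance, so its dispersion falls to the moderation floor — rankings remain
usable, calibrated p-values do not.

### In-frame fusion-read test

For prey k with bait i, the in-frame fusion-read counts are modeled
`Y_c ~ Binomial(F_c, π_c)` in condition c ∈ {S, N}, and the one-sided
hypothesis π_N < π_S is tested with the pooled two-proportion statistic

    ρ = (π̂_S − π̂_N) / sqrt( π̂ (1 − π̂) (1/F_S + 1/F_N) ).

Replicates are pooled (summed) within condition before testing — the model
indexes counts by condition, not replicate. If either condition has no
fusion reads, ρ is undefined and the pair's in-frame score is zero. A zero
pooled variance with unequal proportions maps to a ±1e6 sentinel (only the
rank of ρ matters downstream). For designs without non-selected controls,
`inframe_z_default_null` substitutes the random-cloning null π_N = 1/3
with an effective depth equal to the selected depth F_S (a tunable; the
null proportion reflects one-in-three random reading frames).

### The three scores and the Borda ensemble

All three scores live in [0, 1]; larger is stronger support.

*Enrichment* and *specificity* share a rank-within-rank construction.
Pairs with p ≤ α (default α = 1) form the candidate set G; the p-value
component is `(N − R(p))/N` with ascending competition (minimum) ranks.
G is partitioned into b = α/w windows of similar p (default b = 10;
boundary convention: window l covers ((l−1)w, lw], p = 0 in window 1), and
fold-changes are ranked descending within their window:
`(max R − R(f))/max R`. The combined score adds the fold-change component
scaled by the window's p-score spread divided by the window size, so fold
changes refine but never overturn the p-value ordering; the result is
rescaled by its global maximum. Any pair whose log2 fold-change falls
below the fold-change threshold (default 0) scores zero — depletion is
evidence against an interaction, and without this rule strongly depleted
inert preys (tiny two-sided p) would flood the top of the ranking. A
window whose post-zero p-scores are constant contributes no fold-change
increment.

*Specificity* applies the construction to every ordered bait pair (i, j)
over the selected samples, zeroes triples with f_ijk < 0 or p_ijk > α,
averages over the n_b − 1 comparison baits, and rescales. A promiscuous
(auto-active/sticky) prey is enriched with every bait, so its pairwise
fold-changes hover near zero (negative in about half the directions) and
its specificity collapses.

*In-frame* is the ascending rank of ρ among all pairs with defined ρ,
divided by the maximum rank; undefined ρ scores zero.

*Borda*: within each bait, each available component score is converted to
ascending mid-ranks, ranks are averaged across components, and the mean
rank is rescaled by its per-bait maximum.

Missing p-values are treated as 1 and missing fold-changes as 0 before
scoring (conservative; keeps the score total). Ties are broken
deterministically by prey identifier only in output ordering; tied inputs
receive equal scores.

## The simulator

Each bait × condition × replicate culture is generated as:

1. **Library.** Proportions q are log-normal (σ = 2), renormalized —
   heavy-tailed, spanning ~1e−8 to ~1e−3 for a 20,000-prey library, as in
   real cDNA libraries. A stickiness fraction (default 0.1%) of preys is
   auto-active/non-specific. Selected-condition fitness e ∈ [0, 1] (the
   per-generation division probability): inert preys e ~ Beta(1, 50),
   sticky preys e ~ Beta(8, 4) under every bait; each bait's true
   interactors (uniform 1–20 per bait) get e above the configured
   percentile (default 99.9th) of the pooled fitness draws, uniform up to
   1. Non-selected fitness is a shared e_N = 0.9. The low-concentration
   variant plants true-interactor q at 1e−8 before renormalization.
2. **Growth.** A Galton–Watson pure-birth process: X(0) ~ Binomial(M₀, q)
   with M₀ = 3.84e9 cells, then X(t+1) = X(t) + Binomial(X(t), e) per
   generation until the total population reaches 7.5e10 (non-selected: a
   deterministic generation count from e_N, ≈ 5; selected: a stochastic
   stopping time, ≈ 19 under default conditions, capped at 500 with an
   `extinct` flag rather than an error). Binomial draws at n ~ 1e9 are
   exact RNG draws; generations are synchronous; diploid enrichment and
   the second selection round are treated as deterministic pass-throughs.
3. **Reads.** Z ~ NB(mean L·X, dispersion φ) with L = depth / total cells
   (depth 7.5e6 reads per sample). Non-selected φ_kN is tied to abundance
   through the usual mean–dispersion trend (φ = a₀ + a₁/μ with log-normal
   noise, median anchored at 0.5 for the median prey, capped at 15):
   abundant preys are reproducible across replicates, rare ones noisy.
   Selected φ_ikS is an independent log-normal (median 0.05). The
   high-overdispersion mode instead draws φ_kN ~ U(2.27, 13.42) and
   φ_ikS ~ U(0.33, 2).
4. **Fusion reads.** Per prey, a fusion fraction ~ Beta(2, 60) (mean ≈ 3%
   of reads span the vector–prey junction); f = Binomial(Z, fraction),
   y = Binomial(f, π) with π = 1/3 in non-selection for every prey, and
   under selection π = 0.95 for that bait's true interactors, 1/3 for
   inert preys, and a per-prey U(1/3, 0.95) draw for sticky preys.

Everything is reproducible from a single seed; all distribution parameters
above are plain fields of `ScenarioConfig`.

### What the simulator does and does not emulate

It reproduces: order-of-magnitude library heterogeneity, selection as
differential growth, drift at low initial abundance, NB overdispersion
with a mean–dispersion trend, the small fusion-read fraction, the 1/3
in-frame background, and labeled true / sticky / inert structure. It does
**not** reproduce the empirical joint distributions of (q, φ, e) estimated
from the original screens — those are replaced by the documented parametric
stand-ins. Two consequences matter when comparing with published numbers:
(a) planted true interactors are uniformly strong, so statistical power
saturates at two replicates and the specificity score looks *better* than
reported (published precision-recall values imply a sizable fraction of
marginal trues); (b) the heavy lower tail of q combined with a ~3% fusion
fraction leaves ~20% of trues without non-selected fusion reads, which the
zero rule maps to an in-frame score of 0 — the ideal-scenario in-frame ROC
is therefore ≈ 0.81 here versus 0.99 reported, while the low-concentration
collapse of the in-frame score reproduces quantitatively. Passing tests
validate the machinery and the direction of every effect, not the exact
published operating points.

## Evaluation

Positives are the (bait, prey) true-interactor pairs; every other pair —
explicitly including sticky preys under every bait — is a negative, and
pairs are pooled across baits into one curve. ROC AUC is the trapezoidal
area (equals the mid-rank Mann–Whitney statistic; the suite checks the
equivalence against a brute-force pairwise count). PR AUC is the step-wise
non-interpolated estimator (average precision), unbiased under the heavy
class imbalance of screens (prevalence ~5e−4), where it converges to the
prevalence for uninformative scores.

## Normalization toolbox

Counts-per-million library-size scaling; TPM given prey fragment lengths
(identical to CPM when lengths are equal); median-of-ratios size factors
computed within bait × condition replicate groups with geometric means over
preys positive in all group samples; and replicate-based RUV (log(x+1)
counts centered within replicate groups, SVD of the centered matrix, top-k
sample directions regressed out, back-transformed, zeros preserved;
default grouping: selected samples by bait, all non-selected together,
k = 1). Diagnostics: per-prey CV across replicates (sd/mean, ddof = 1,
zero-mean preys reported missing), pairwise Pearson correlations within
condition, and paired Wilcoxon signed-rank comparisons of CV distributions
(exact for ≤ 25 informative pairs, else normal approximation with
continuity correction). CVs are computed on untransformed normalized
counts. A PCA helper (centered, unscaled, on log2(x+1)) is plumbing for
quick sample maps.

## Numerical and design choices

- Size factors are normalized to geometric mean 1, so offsets and reported
  base means share the counts' scale.
- Window membership uses half-open intervals; competition (minimum) ranks
  for ties throughout the score chain; mid-ranks only in the Borda step
  (classic Borda with ties).
- The specificity combination is computed per ordered triple and then
  averaged over comparison baits (the window term is triple-specific).
- Window spread terms use post-zero p-scores, so a window whose members
  are all zeroed contributes nothing.
- p-values below float underflow tie at zero; their relative order is then
  decided by the fold-change component, which is the intended behavior.
- Problem sizes in the validation suite: scenario checks simulate the full
  20,000-prey, 10-bait design with three seeds each (PR values are
  prevalence-sensitive, so scaled-down libraries are only used for
  ordering checks); calibration checks use 500–2,000 preys.

## Known limitations

- Wald p-values from pseudo-replicated designs are anti-conservative by
  construction; use them for ranking only.
- The NB engine supports exactly two groups per contrast (all the score
  system needs); no GLM designs with covariates.
- RUV-normalized matrices are not integer counts; feeding them to the NB
  stage rounds them (warned). The intended route is raw counts plus size
  factors.
- The simulator's stand-in parameter distributions are documented
  approximations; absolute PR operating points depend on them strongly
  (see above).
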