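# y2hscreen

Scoring and simulation of next-generation yeast two-hybrid interaction
screens (Y2H-NGIS).

In a batch Y2H-NGIS screen, a diploid yeast population carrying one bait
and a cDNA prey library is grown with and without reporter selection, and
prey cDNA is deep-sequenced from both cultures. The raw signal — prey read
counts — confounds true bait–prey interactions with library composition,
auto-active preys (which switch the reporter on without any interaction)
and sticky preys (which bind everything). `y2hscreen` turns the count
tables into a ranked candidate list using three complementary scores per
(bait, prey) pair, each in [0, 1]:

- **Enrichment** `E_ik` — ranks of log2 fold-change nested within ranks of
  Wald p-values from a negative binomial contrast of selected vs.
  non-selected counts (`Z ~ NB(s·m, α)`, gene-wise Cox–Reid dispersion with
  empirical-Bayes moderation toward a mean–dispersion trend).
- **Specificity** `S_ik` — the same rank-within-rank construction applied
  to every pairwise contrast between selected baits and averaged over the
  n_b − 1 comparison baits; preys with `f_ijk < 0` or `p_ijk > α` are
  hard-zeroed, so promiscuous preys collapse.
- **In-frame** `IF_ik` — the rank of the pooled two-proportion statistic
  `ρ = (π̂_S − π̂_N)/√(π̂(1−π̂)(1/F_S + 1/F_N))` testing whether the
  in-frame fraction of fusion reads rises above the random-cloning
  background π_N ≈ 1/3 under selection.

A Borda (mean-rank) ensemble combines whichever scores the experimental
design supports. The package also ships a generative simulator — library
proportions spanning orders of magnitude, Galton–Watson growth under
per-prey fitness, negative binomial read counts, binomial fusion reads —
so the whole pipeline can be validated end to end against known truth
labels. See `docs/methods.md` for the models, parameter defaults and known
limitations.

## Worked example

`examples/score_screen.py` simulates a 1,000-prey, 2-bait screen with 4–8
planted true interactors per bait, runs the full pipeline and prints the
per-bait Borda ranking next to the truth labels:

```
top 8 candidates for bait00  (E=enrichment S=specificity IF=in-frame)
  prey00131  E=0.996  S=1.000  IF=1.000  borda=1.000  [true_interactor]
  prey00942  E=0.934  S=0.992  IF=0.995  borda=0.998  [true_interactor]
  prey00240  E=0.698  S=0.994  IF=0.990  borda=0.997  [true_interactor]
  prey00529  E=0.527  S=0.989  IF=0.992  borda=0.996  [true_interactor]
  prey00500  E=0.645  S=0.776  IF=0.985  borda=0.947  [auto_active_nonspecific]
  ...
9 of the 11 planted true interactors appear in the per-bait top-8 lists.
```

True interactors fill the top of the ranking; the auto-active prey is the
one high scorer with visibly depressed specificity (it is enriched with
*both* baits, so the bait-vs-bait contrast penalizes it — the more baits
in the screen, the sharper this penalty). The other examples demonstrate
the simulator (`simulate_screen.py`), the normalization toolbox and its
replicate-agreement diagnostics (`normalize_counts.py`), the in-frame test
on hand-sized numbers (`inframe_test.py`) and truth-label evaluation with
ROC / precision-recall curves (`evaluate_scenario.py`).

## Command line

Every stage is also a subcommand working on plain TSV tables, with a
provenance YAML written next to each output:

```sh
y2hscreen simulate --config scenario.yaml --seed 1 --out sim/
y2hscreen normalize --counts counts.tsv --metadata meta.tsv \
    --method median_of_ratios --out norm.tsv
y2hscreen fit --counts counts.tsv --metadata meta.tsv \
    --contrast enrichment --out enrich.tsv
y2hscreen fit --counts counts.tsv --metadata meta.tsv \
    --contrast specificity --out spec.tsv
y2hscreen inframe --fusion fusion.tsv --counts counts.tsv \
    --metadata meta.tsv --out rho.tsv
y2hscreen score --enrich-results enrich.tsv --spec-results spec.tsv \
    --inframe-results rho.tsv --out scores.tsv
```

Score defaults mirror the published settings: `--enrich_p_val 1`,
`--enrich_fold_change 0`, `--spec_p_val 1`, `--spec_fold_change 0`,
ten p-value windows. Designs without replicates can pass
`--pseudo-replicates` to `fit`; screens without non-selected controls can
use `inframe --assume-null-third`.

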