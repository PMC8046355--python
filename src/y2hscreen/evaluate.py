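"""ROC / precision-recall evaluation of scores against simulated truth.

Positives are the (bait, prey) true-interactor pairs; every other pair —
including auto-active / non-specific preys — is a negative, so the curves
measure the ability to separate true from promiscuous binders, not merely
from background. Pairs are pooled across baits into a single curve.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn import metrics

from .enrichment import fit_all_enrichment, fit_specificity_pairs
from .fusion import inframe_stats_fast
from .scores import ScoreParams, compute_score_table
from .simulate import LABEL_TRUE, ScenarioConfig, SimulatedDataset, simulate_experiment

SCORE_NAMES = ("enrichment", "specificity", "inframe", "borda")


@dataclasses.dataclass
class EvalResult:
    scenario: str
    score: str
    roc_auc: float
    pr_auc: float
    n_positives: int
    n_total: int
    seed: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal ROC AUC; ties follow the mid-rank (Mann-Whitney) rule."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC needs at least one positive and one negative")
    return float(metrics.roc_auc_score(labels, scores))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("PR AUC needs at least one positive")
    return float(metrics.average_precision_score(labels, scores))


def score_dataset(
    dataset: SimulatedDataset, params: ScoreParams | None = None
) -> pd.DataFrame:
    """Full pipeline on a simulated screen: NB fits, in-frame test, scores."""
    params = params or ScoreParams()
    cm = dataset.counts
    enrich = fit_all_enrichment(cm)
    pairwise = fit_specificity_pairs(cm) if len(cm.baits) >= 2 else None
    rho = inframe_stats_fast(dataset.fusion, cm)
    return compute_score_table(enrich, pairwise, rho, params)


def evaluate_scores(
    score_table: pd.DataFrame, truth_labels: pd.DataFrame
) -> pd.DataFrame:
    """ROC / PR AUC per score column, pooled over all (bait, prey) pairs."""
    merged = score_table.merge(truth_labels, on=["bait", "prey"], how="left")
    y = (merged["label"] == LABEL_TRUE).to_numpy()
    rows = []
    for name in SCORE_NAMES:
        s = merged[name].to_numpy()
        rows.append(
            {
                "score": name,
                "roc_auc": roc_auc(s, y),
                "pr_auc": pr_auc(s, y),
                "n_positives": int(y.sum()),
                "n_total": int(len(y)),
            }
        )
    return pd.DataFrame(rows)


def run_scenario(
    config: ScenarioConfig,
    params: ScoreParams | None = None,
    seeds: tuple[int, ...] = (1, 2, 3),
    scenario_id: str = "scenario",
) -> list[EvalResult]:
    """Simulate, fit, score and evaluate one scenario for each seed."""
    results = []
    for seed in seeds:
        dataset = simulate_experiment(config, seed=seed)
        table = score_dataset(dataset, params)
        ev = evaluate_scores(table, dataset.truth.labels)
        for row in ev.itertuples():
            results.append(
                EvalResult(
                    scenario=scenario_id,
                    score=row.score,
                    roc_auc=row.roc_auc,
                    pr_auc=row.pr_auc,
                    n_positives=row.n_positives,
                    n_total=row.n_total,
                    seed=seed,
                )
            )
    return results


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def mean_auc(results: list[EvalResult], score: str, metric: str = "roc_auc") -> float:
    vals = [getattr(r, metric) for r in results if r.score == score]
    if not vals:
        raise ValueError(f"no results for score {score!r}")
    return float(np.mean(vals))
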