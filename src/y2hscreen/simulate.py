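"""Generative simulator of deep-sequenced yeast two-hybrid screens.

Each bait x condition x replicate culture starts from M0 cells allocated to
preys by a Binomial split of the library proportions q, grows as a
Galton-Watson pure-birth branching process (per generation each cell
divides with probability e, the prey's fitness in that condition), and is
sequenced at depth V: observed counts are negative binomial around
L * X(T), where L = V / M(T) converts cells to expected reads and the
per-prey overdispersion phi captures variation beyond the branching noise.
Fusion reads are a small binomial fraction of each prey's reads, and the
in-frame fraction of those is 1/3 under non-selection (random three-frame
cloning) but elevated under selection for preys genuinely translated in
frame with the activation domain.

Truth labels per (bait, prey): ``true_interactor`` (high fitness only with
its bait), ``auto_active_nonspecific`` (high fitness with every bait) and
``inert`` (near-zero fitness under selection). Library proportions span
orders of magnitude (log-normal), as real cDNA libraries do.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, FusionTable, SampleMeta

LABEL_TRUE = "true_interactor"
LABEL_STICKY = "auto_active_nonspecific"
LABEL_INERT = "inert"


@dataclasses.dataclass
class ScenarioConfig:
    """Parameters of one simulated screen scenario.

    Defaults reproduce the idealized screen: 10 baits, 3 replicates,
    a 20,000-prey library, 1-20 true interactors per bait, 0.1% sticky
    preys, true-interactor fitness above the 99.9th percentile of the
    fitness pool, 7.5 million reads per sample.
    """

    n_preys: int = 20_000
    n_baits: int = 10
    n_replicates: int = 3
    interactors_min: int = 1
    interactors_max: int = 20
    stickiness: float = 0.001
    strength_percentile: float = 0.999
    overdispersion_mode: str = "random"  # "random" | "high"
    low_concentration: bool = False
    low_q: float = 1e-8
    m0: float = 3.84e9
    target_population: float = 7.5e10
    depth: float = 7.5e6
    fitness_non_selected: float = 0.9
    # parametric stand-ins for the empirical library distributions
    q_sigma: float = 2.0  # log-normal spread of library proportions
    inert_fitness_beta: tuple[float, float] = (1.0, 50.0)
    sticky_fitness_beta: tuple[float, float] = (8.0, 4.0)
    fusion_fraction_beta: tuple[float, float] = (2.0, 60.0)
    inframe_true: float = 0.95
    phi_sigma: float = 1.0  # log-normal spread of overdispersion draws
    phi_median_nonsel: float = 0.5
    phi_median_sel: float = 0.05
    phi_trend_a0: float = 0.01  # asymptotic dispersion of abundant preys
    phi_max: float = 15.0
    phi_high_nonsel: tuple[float, float] = (2.27, 13.42)
    phi_high_sel: tuple[float, float] = (0.33, 2.0)
    max_generations: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.stickiness < 1):
            raise ValueError("stickiness must lie in [0, 1)")
        if not (0 < self.strength_percentile < 1):
            raise ValueError("strength percentile must lie in (0, 1)")
        if self.m0 >= self.target_population:
            raise ValueError("initial cells must be below the target population")
        if self.interactors_min < 1 or self.interactors_max < self.interactors_min:
            raise ValueError("invalid true-interactor range")
        frac = self.stickiness + self.interactors_max / self.n_preys
        if frac >= 1:
            raise ValueError("stickiness plus interactor fraction must be < 1")
        if self.overdispersion_mode not in ("random", "high"):
            raise ValueError("overdispersion_mode must be 'random' or 'high'")


@dataclasses.dataclass
class TruthTable:
    """Generating parameters and labels of a simulated screen."""

    preys: list[str]
    baits: list[str]
    labels: pd.DataFrame  # bait, prey, label
    q: np.ndarray  # (n_baits, n_preys), rows sum to 1
    fitness_selected: np.ndarray  # (n_baits, n_preys) in [0, 1]
    fitness_non_selected: float
    phi_nonsel: np.ndarray  # (n_preys,)
    phi_sel: np.ndarray  # (n_baits, n_preys)
    inframe_selected: np.ndarray  # (n_preys,)
    fusion_fraction: np.ndarray  # (n_preys,)

    def positives(self) -> pd.DataFrame:
        return self.labels[self.labels["label"] == LABEL_TRUE]


@dataclasses.dataclass
class GrowthState:
    """Endpoint of one replicate culture."""

    cells: np.ndarray  # X_k(T), int64 per prey
    generations: int
    size_factor: float  # L = depth / total cells
    extinct: bool


@dataclasses.dataclass
class SimulatedDataset:
    counts: CountMatrix
    fusion: FusionTable
    truth: TruthTable
    config: ScenarioConfig
    flags: list[str]


def sample_library(config: ScenarioConfig, rng: np.random.Generator) -> TruthTable:
    """Draw library proportions, labels and generating parameters.

    Library proportions are log-normal (heavy-tailed, spanning orders of
    magnitude). The fitness pool for the strength percentile is the union of
    inert and sticky fitness draws; true interactors sit above the
    configured percentile of that pool.
    """
    n_p, n_b = config.n_preys, config.n_baits
    preys = [f"prey{k:05d}" for k in range(n_p)]
    baits = [f"bait{i:02d}" for i in range(n_b)]

    q_base = rng.lognormal(mean=0.0, sigma=config.q_sigma, size=n_p)
    q_base /= q_base.sum()

    sticky = rng.random(n_p) < config.stickiness
    a_in, b_in = config.inert_fitness_beta
    a_st, b_st = config.sticky_fitness_beta
    fitness = rng.beta(a_in, b_in, size=(n_b, n_p))
    fitness[:, sticky] = rng.beta(a_st, b_st, size=(n_b, int(sticky.sum())))

    pool = fitness.ravel()
    threshold = float(np.quantile(pool, config.strength_percentile))

    label_rows = []
    q = np.tile(q_base, (n_b, 1))
    true_mask = np.zeros((n_b, n_p), dtype=bool)
    eligible = np.flatnonzero(~sticky)
    for i in range(n_b):
        n_true = int(rng.integers(config.interactors_min, config.interactors_max + 1))
        chosen = rng.choice(eligible, size=n_true, replace=False)
        true_mask[i, chosen] = True
        fitness[i, chosen] = threshold + rng.random(n_true) * (1.0 - threshold)
        if config.low_concentration:
            q[i, chosen] = config.low_q
            q[i] /= q[i].sum()
    for i, bait in enumerate(baits):
        lab = np.where(
            true_mask[i], LABEL_TRUE, np.where(sticky, LABEL_STICKY, LABEL_INERT)
        )
        label_rows.append(pd.DataFrame({"bait": bait, "prey": preys, "label": lab}))

    if config.overdispersion_mode == "high":
        lo, hi = config.phi_high_nonsel
        phi_n = rng.uniform(lo, hi, size=n_p)
        lo, hi = config.phi_high_sel
        phi_s = rng.uniform(lo, hi, size=(n_b, n_p))
    else:
        # non-selected overdispersion is sampled jointly with abundance via
        # the usual mean-dispersion trend phi = a0 + a1/mu (abundant preys
        # are reproducible, rare ones noisy), anchored so the median prey
        # has the configured median dispersion; selected-condition
        # overdispersion is an independent log-normal draw
        mu_expected = np.maximum(q_base * config.depth, 1e-3)
        a0 = config.phi_trend_a0
        a1 = max(config.phi_median_nonsel - a0, 0.0) * np.median(mu_expected)
        trend = a0 + a1 / mu_expected
        phi_n = np.minimum(
            trend * rng.lognormal(0.0, config.phi_sigma, n_p), config.phi_max
        )
        phi_s = rng.lognormal(
            np.log(config.phi_median_sel), config.phi_sigma, (n_b, n_p)
        )

    pi_sel = np.full(n_p, 1.0 / 3.0)
    pi_sel[sticky] = rng.uniform(1.0 / 3.0, config.inframe_true, int(sticky.sum()))
    # per-bait true interactors get the strongly in-frame proportion at
    # simulation time (pi depends on the bait through the label)

    a_f, b_f = config.fusion_fraction_beta
    fusion_fraction = rng.beta(a_f, b_f, size=n_p)

    return TruthTable(
        preys=preys,
        baits=baits,
        labels=pd.concat(label_rows, ignore_index=True),
        q=q,
        fitness_selected=fitness,
        fitness_non_selected=config.fitness_non_selected,
        phi_nonsel=phi_n,
        phi_sel=phi_s,
        inframe_selected=pi_sel,
        fusion_fraction=fusion_fraction,
    )


def simulate_growth(
    q: np.ndarray,
    fitness: np.ndarray | float,
    config: ScenarioConfig,
    rng: np.random.Generator,
    deterministic_generations: int | None = None,
) -> GrowthState:
    """Grow one culture to the target population.

    ``deterministic_generations`` fixes T (used in the non-selected
    condition where all preys share the fitness e_N); otherwise generations
    accrue until the total population reaches the target or the generation
    cap is hit (a culture that cannot grow is flagged extinct, not an
    error).
    """
    m0 = int(config.m0)
    x = rng.binomial(m0, q).astype(np.int64)
    e = np.broadcast_to(np.asarray(fitness, dtype=float), x.shape)
    target = config.target_population
    t = 0
    if deterministic_generations is not None:
        for _ in range(deterministic_generations):
            x = x + rng.binomial(x, e)
            t += 1
    else:
        while x.sum() < target and t < config.max_generations:
            x = x + rng.binomial(x, e)
            t += 1
    total = int(x.sum())
    extinct = total == 0
    size_factor = config.depth / total if total > 0 else 0.0
    return GrowthState(cells=x, generations=t, size_factor=size_factor, extinct=extinct)


def non_selected_generations(config: ScenarioConfig) -> int:
    """Deterministic generation count for the shared non-selected fitness."""
    growth = 1.0 + config.fitness_non_selected
    return int(
        np.ceil(np.log(config.target_population / config.m0) / np.log(growth))
    )


def simulate_reads(
    growth: GrowthState,
    phi: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """NB read counts with mean L * X and variance mu + phi * mu^2."""
    mu = growth.size_factor * growth.cells.astype(float)
    z = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    over = pos & (phi > 0)
    poisson_only = pos & (phi <= 0)
    if over.any():
        lam = rng.gamma(shape=1.0 / phi[over], scale=phi[over] * mu[over])
        z[over] = rng.poisson(lam)
    if poisson_only.any():
        z[poisson_only] = rng.poisson(mu[poisson_only])
    return z


def simulate_fusion(
    counts_column: np.ndarray,
    fusion_fraction: np.ndarray,
    inframe_pi: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fusion totals f = Bin(Z, fraction) and in-frame reads y = Bin(f, pi)."""
    f = rng.binomial(counts_column, fusion_fraction)
    y = rng.binomial(f, inframe_pi)
    return y, f


def simulate_experiment(
    config: ScenarioConfig, seed: int | np.random.SeedSequence | None = None
) -> SimulatedDataset:
    """Run the full screen: every bait x condition x replicate culture.

    Fully reproducible from the seed (``config.seed`` is used when no seed
    is passed).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    truth = sample_library(config, rng)
    n_p = config.n_preys
    t_non = non_selected_generations(config)

    pi_non = np.full(n_p, 1.0 / 3.0)
    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    fusion_rows: list[pd.DataFrame] = []
    flags: list[str] = []

    true_by_bait = {
        i: (truth.labels[truth.labels["bait"] == bait]["label"] == LABEL_TRUE)
        .to_numpy()
        for i, bait in enumerate(truth.baits)
    }

    for i, bait in enumerate(truth.baits):
        pi_sel = truth.inframe_selected.copy()
        pi_sel[true_by_bait[i]] = config.inframe_true
        for condition in ("non_selected", "selected"):
            for r in range(1, config.n_replicates + 1):
                if condition == "non_selected":
                    growth = simulate_growth(
                        truth.q[i],
                        truth.fitness_non_selected,
                        config,
                        rng,
                        deterministic_generations=t_non,
                    )
                    phi = truth.phi_nonsel
                    pi = pi_non
                else:
                    growth = simulate_growth(
                        truth.q[i], truth.fitness_selected[i], config, rng
                    )
                    phi = truth.phi_sel[i]
                    pi = pi_sel
                sample_id = f"{bait}_{'S' if condition == 'selected' else 'N'}_r{r}"
                if growth.extinct:
                    flags.append(f"extinct culture: {sample_id}")
                z = simulate_reads(growth, phi, config, rng)
                y, f = simulate_fusion(z, truth.fusion_fraction, pi, rng)
                columns[sample_id] = z
                samples.append(
                    SampleMeta(
                        sample_id=sample_id,
                        bait=bait,
                        condition=condition,
                        replicate=r,
                    )
                )
                nz = f > 0
                fusion_rows.append(
                    pd.DataFrame(
                        {
                            "prey": np.asarray(truth.preys)[nz],
                            "sample": sample_id,
                            "inframe_reads": y[nz],
                            "fusion_reads": f[nz],
                        }
                    )
                )

    counts = CountMatrix(
        pd.DataFrame(columns, index=truth.preys), samples, normalized_by="none"
    )
    fusion = FusionTable(
        pd.concat(fusion_rows, ignore_index=True)
        if fusion_rows
        else pd.DataFrame(columns=FusionTable.COLUMNS)
    )
    return SimulatedDataset(
        counts=counts, fusion=fusion, truth=truth, config=config, flags=flags
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write counts, metadata, fusion and truth tables as TSV. Plumbing."""
    from pathlib import Path

    from . import io_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_tables.write_counts(
        dataset.counts, outdir / "counts.tsv", outdir / "metadata.tsv"
    )
    io_tables.write_fusion(dataset.fusion, outdir / "fusion.tsv")
    dataset.truth.labels.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def scenario_from_dict(d: dict) -> ScenarioConfig:
    fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown scenario parameters: {sorted(unknown)}")
    for key in ("inert_fitness_beta", "sticky_fitness_beta", "fusion_fraction_beta",
                "phi_high_nonsel", "phi_high_sel"):
        if key in d and isinstance(d[key], Iterable):
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)
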