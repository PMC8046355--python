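import numpy as np
import pandas as pd
import pytest

from y2hscreen.io_tables import CountMatrix, FusionTable, SampleMeta


def make_meta(n_baits=2, n_reps=2, conditions=("non_selected", "selected")):
    metas = []
    for b in range(n_baits):
        for cond in conditions:
            for r in range(1, n_reps + 1):
                tag = "S" if cond == "selected" else "N"
                metas.append(
                    SampleMeta(f"b{b}_{tag}{r}", f"bait{b}", cond, r)
                )
    return metas


def make_counts(n_preys=6, n_baits=2, n_reps=2, seed=0, lam=50.0):
    rng = np.random.default_rng(seed)
    metas = make_meta(n_baits, n_reps)
    df = pd.DataFrame(
        rng.poisson(lam, size=(n_preys, len(metas))),
        index=[f"p{k}" for k in range(n_preys)],
        columns=[m.sample_id for m in metas],
    )
    return CountMatrix(df, metas)


@pytest.fixture
def small_counts():
    return make_counts()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fusion_table(small_counts):
    rows = []
    rng = np.random.default_rng(7)
    for prey in small_counts.preys:
        for sid in small_counts.sample_ids:
            f = int(rng.integers(0, 30))
            y = int(rng.integers(0, f + 1)) if f else 0
            rows.append((prey, sid, y, f))
    return FusionTable(
        pd.DataFrame(rows, columns=FusionTable.COLUMNS)
    )
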