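"""Tabular input/output for screen count data, fusion reads and score tables.

All files are tab-separated UTF-8 text. A count matrix is stored wide
(first column = prey identifier, one column per sample); sample metadata
lives in a separate three-plus-column table mapping ``sample_id`` to
``(bait, condition, replicate)``; fusion reads are stored long, one row per
(prey, sample).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("selected", "non_selected")


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing sample in the screen."""

    sample_id: str
    bait: str
    condition: str  # "selected" | "non_selected"
    replicate: int
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


class CountMatrix:
    """Preys x samples read-count matrix with per-sample metadata.

    Raw matrices hold non-negative integers; normalized matrices hold
    non-negative reals and record the method in ``normalized_by``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta],
        normalized_by: str = "none",
    ) -> None:
        samples = list(samples)
        if list(counts.columns) != [s.sample_id for s in samples]:
            raise ValueError("count columns do not match sample metadata order")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate prey identifier {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"non-numeric count at prey {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at prey {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}"
            )
        if normalized_by == "none":
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integers")
            counts = counts.round().astype(np.int64)
        self.counts = counts
        self.samples = samples
        self.normalized_by = normalized_by

    # -- convenience ------------------------------------------------------
    @property
    def preys(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def baits(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.bait not in out:
                out.append(s.bait)
        return out

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_index(
        self, bait: str | None = None, condition: str | None = None
    ) -> np.ndarray:
        """Positional indices of samples matching bait and/or condition."""
        keep = []
        for i, s in enumerate(self.samples):
            if bait is not None and s.bait != bait:
                continue
            if condition is not None and s.condition != condition:
                continue
            keep.append(i)
        return np.asarray(keep, dtype=int)

    def replicate_groups(self) -> dict[tuple[str, str], list[int]]:
        """Sample indices grouped by (bait, condition), in metadata order."""
        groups: dict[tuple[str, str], list[int]] = {}
        for i, s in enumerate(self.samples):
            groups.setdefault((s.bait, s.condition), []).append(i)
        return groups

    def with_counts(self, counts: pd.DataFrame, normalized_by: str) -> "CountMatrix":
        return CountMatrix(counts, self.samples, normalized_by=normalized_by)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.normalized_by == other.normalized_by
            and self.counts.equals(other.counts)
        )


class FusionTable:
    """Long table of in-frame (y) out of total (f) fusion reads per (prey, sample)."""

    COLUMNS = ["prey", "sample", "inframe_reads", "fusion_reads"]

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"fusion table missing columns: {missing}")
        table = table[self.COLUMNS].copy()
        y = table["inframe_reads"].to_numpy()
        f = table["fusion_reads"].to_numpy()
        if not (np.allclose(y, np.round(y)) and np.allclose(f, np.round(f))):
            raise ValueError("fusion read counts must be integers")
        table["inframe_reads"] = table["inframe_reads"].astype(np.int64)
        table["fusion_reads"] = table["fusion_reads"].astype(np.int64)
        if (table["inframe_reads"] < 0).any() or (table["fusion_reads"] < 0).any():
            raise ValueError("fusion read counts must be non-negative")
        bad = table["inframe_reads"] > table["fusion_reads"]
        if bad.any():
            row = table[bad].iloc[0]
            raise ValueError(
                f"in-frame reads exceed total fusion reads for prey "
                f"{row['prey']!r}, sample {row['sample']!r} "
                f"({row['inframe_reads']} > {row['fusion_reads']})"
            )
        self.table = table.reset_index(drop=True)

    def aggregate(self, counts: CountMatrix) -> pd.DataFrame:
        """Sum y and f per (bait, prey, condition) across replicates.

        Preys absent from the fusion table get y = f = 0 (which downstream
        maps to an in-frame score of zero).
        """
        meta = {s.sample_id: s for s in counts.samples}
        unknown = set(self.table["sample"]) - set(meta)
        if unknown:
            raise ValueError(f"fusion table references unknown samples: {sorted(unknown)}")
        t = self.table.copy()
        t["bait"] = [meta[s].bait for s in t["sample"]]
        t["condition"] = [meta[s].condition for s in t["sample"]]
        agg = (
            t.groupby(["bait", "prey", "condition"], as_index=False)[
                ["inframe_reads", "fusion_reads"]
            ].sum()
        )
        full = pd.MultiIndex.from_product(
            [counts.baits, counts.preys, CONDITIONS],
            names=["bait", "prey", "condition"],
        )
        agg = (
            agg.set_index(["bait", "prey", "condition"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
        return agg

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FusionTable):
            return NotImplemented
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_metadata(meta_path: str | Path) -> list[SampleMeta]:
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "bait": str})
    needed = {"sample_id", "bait", "condition", "replicate"}
    missing = needed - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    pseudo = meta["pseudo"] if "pseudo" in meta.columns else [False] * len(meta)
    return [
        SampleMeta(
            sample_id=row.sample_id,
            bait=row.bait,
            condition=row.condition,
            replicate=int(row.replicate),
            pseudo=bool(p),
        )
        for row, p in zip(meta.itertuples(), pseudo)
    ]


def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a wide prey x sample count table plus its sample metadata.

    Sample order follows the metadata file; every metadata sample must be a
    column of the count table and vice versa.
    """
    samples = read_metadata(meta_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    meta_ids = [s.sample_id for s in samples]
    missing = set(df.columns) - set(meta_ids)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    absent = set(meta_ids) - set(df.columns)
    if absent:
        raise ValueError(f"metadata samples missing from count table: {sorted(absent)}")
    df = df[meta_ids]
    normalized_by = "none"
    arr = df.to_numpy()
    if np.issubdtype(arr.dtype, np.floating) and not np.allclose(
        arr, np.round(arr), equal_nan=True
    ):
        normalized_by = "unknown"
    return CountMatrix(df, samples, normalized_by=normalized_by)


def write_counts(
    cm: CountMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    out = cm.counts.copy()
    out.index.name = "prey"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        pd.DataFrame(
            [dataclasses.asdict(s) for s in cm.samples]
        ).to_csv(meta_path, sep="\t", index=False)


def read_fusion(path: str | Path) -> FusionTable:
    df = pd.read_csv(path, sep="\t", dtype={"prey": str, "sample": str})
    return FusionTable(df)


def write_fusion(ft: FusionTable, path: str | Path) -> None:
    ft.table.to_csv(path, sep="\t", index=False)


SCORE_COLUMNS = ["bait", "prey", "enrichment", "specificity", "inframe", "borda"]


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a score table, ordered by bait then descending Borda ensemble.

    Final ties broken by prey identifier for reproducible output.
    """
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    out = table[SCORE_COLUMNS].copy()
    out = out.sort_values(
        ["bait", "borda", "prey"], ascending=[True, False, True]
    ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"bait": str, "prey": str})
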