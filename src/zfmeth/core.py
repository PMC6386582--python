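"""Shared containers: genomic intervals and grouped count matrices.

Coordinate convention: every in-memory interval is 0-based, half-open
``[start, end)``.  Conversions to 1-based formats (GFF3, cytosine reports)
happen only at file boundaries (:mod:`zfmeth.fileio`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "CountMatrix", "interval_sort_key", "overlaps"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region.

    ``summit`` (optional) is the single-bp point of maximal signal for
    peak-like intervals; ``strand`` is '+', '-' or None.
    """

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def interval_sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


class CountMatrix:
    """Features x samples non-negative integer counts with a sample->group map.

    Thin wrapper around a pandas DataFrame (rows = feature IDs, columns =
    sample IDs).  Exactly two groups are required only where a two-group
    test is run, not at construction.
    """

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, str]):
        counts = counts.copy()
        if counts.shape[1] == 0:
            raise ValueError("count matrix has no samples")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        missing = [s for s in counts.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        self.counts = counts
        self.groups = {s: groups[s] for s in counts.columns}

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.counts.columns if self.groups[s] == group]
        if not out:
            raise ValueError(f"group {group!r} has zero samples")
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountMatrix({self.counts.shape[0]} features x "
            f"{self.counts.shape[1]} samples, groups={self.group_names})"
        )


def concat_matrices(frames: Iterable[tuple[pd.DataFrame, str]]) -> CountMatrix:
    """Join per-group count frames (same feature index) into one CountMatrix.

    ``frames`` yields (counts, group_name); sample columns are prefixed with
    the group name when they collide.
    """
    pieces = []
    groups: dict[str, str] = {}
    for df, group in frames:
        df = df.copy()
        renames = {}
        for col in df.columns:
            name = col if col not in groups else f"{group}:{col}"
            renames[col] = name
            groups[name] = group
        df = df.rename(columns=renames)
        pieces.append(df)
    joined = pd.concat(pieces, axis=1)
    if joined.isna().any().any():
        raise ValueError("feature indices of the frames do not match")
    return CountMatrix(joined, groups)
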