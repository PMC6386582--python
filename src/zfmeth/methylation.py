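"""Per-cytosine and per-region bisulfite methylation quantification.

Context assignment (CG / CHG / CHH, H = A, T or C), conversion-failure read
filtering, #C/(#C+#T) ratios with optional coverage gating, and pooled
region summaries for amplicon (BS-PCR) style analyses.

Cytosine tables are pandas DataFrames with columns
``chrom, pos (1-based), strand, context, count_m, count_u`` — the layout of
a per-cytosine methylation extractor report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval

__all__ = [
    "CONTEXTS",
    "NOT_A_CYTOSINE",
    "BisulfiteRead",
    "RegionMethylation",
    "assign_context",
    "genome_cytosine_table",
    "is_conversion_failure",
    "filter_conversion_failures",
    "cytosine_ratio",
    "methylation_levels",
    "region_summary",
    "combine_bspcr_regions",
]

CONTEXTS = ("CG", "CHG", "CHH")

#: Sentinel returned by :func:`assign_context` when the queried base is not a
#: cytosine on the queried strand.  Edge positions whose context cannot be
#: resolved from the available downstream bases return ``None`` instead.
NOT_A_CYTOSINE = "not_a_cytosine"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _context_from_downstream(d1: str | None, d2: str | None) -> str | None:
    """Context from the two bases 5'->3' downstream of a cytosine.

    Missing bases (chromosome edge) yield None when more than one context
    remains possible.
    """
    if d1 is None:
        return None
    if d1 == "G":
        return "CG"
    # d1 is H (A, T or C): CHG vs CHH hinges on the second base.
    if d2 is None:
        return None
    return "CHG" if d2 == "G" else "CHH"


def assign_context(
    genome: Mapping[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """Sequence context of the cytosine at 1-based ``pos`` on ``strand``.

    Returns one of ``CG``/``CHG``/``CHH``, :data:`NOT_A_CYTOSINE` if the
    base on that strand is not a C, or ``None`` for 3'-edge positions whose
    context is unresolvable.
    """
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside {chrom} (len {len(seq)})")
    i = pos - 1
    base = seq[i].upper()
    if strand == "+":
        if base != "C":
            return NOT_A_CYTOSINE
        d1 = seq[i + 1].upper() if i + 1 < len(seq) else None
        d2 = seq[i + 2].upper() if i + 2 < len(seq) else None
        return _context_from_downstream(d1, d2)
    if strand == "-":
        if base != "G":  # G on plus strand is C on minus
            return NOT_A_CYTOSINE
        d1 = seq[i - 1].translate(_COMPLEMENT).upper() if i - 1 >= 0 else None
        d2 = seq[i - 2].translate(_COMPLEMENT).upper() if i - 2 >= 0 else None
        return _context_from_downstream(d1, d2)
    raise ValueError(f"invalid strand: {strand!r}")


def genome_cytosine_table(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines of one chromosome (both strands) with their contexts.

    Vectorised equivalent of calling :func:`assign_context` at every
    position; edge positions with unresolvable context are excluded.
    Returns columns ``pos`` (1-based), ``strand``, ``context``.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    n = arr.size
    is_c = arr == b"C"
    is_g = arr == b"G"

    rows: list[pd.DataFrame] = []
    # plus strand: downstream = i+1, i+2
    if n >= 3:
        idx = np.nonzero(is_c[: n - 2])[0]
        d1g = is_g[idx + 1]
        d2g = is_g[idx + 2]
        ctx = np.where(d1g, "CG", np.where(d2g, "CHG", "CHH"))
        rows.append(
            pd.DataFrame({"pos": idx + 1, "strand": "+", "context": ctx})
        )
    # minus strand: downstream = i-1, i-2 complemented (G on plus == C there)
    if n >= 3:
        idx = np.nonzero(is_g[2:])[0] + 2
        d1g = is_c[idx - 1]  # complement of plus-strand C is G
        d2g = is_c[idx - 2]
        ctx = np.where(d1g, "CG", np.where(d2g, "CHG", "CHH"))
        rows.append(
            pd.DataFrame({"pos": idx + 1, "strand": "-", "context": ctx})
        )
    # edge positions, resolved individually where possible
    genome = {chrom: seq}
    edge: list[tuple[int, str, str]] = []
    for pos in {n - 1, n, 1, 2} & set(range(1, n + 1)):
        for strand in "+-":
            already = (strand == "+" and pos <= n - 2) or (
                strand == "-" and pos >= 3
            )
            if already:
                continue
            ctx = assign_context(genome, chrom, pos, strand)
            if ctx in CONTEXTS:
                edge.append((pos, strand, ctx))
    if edge:
        rows.append(pd.DataFrame(edge, columns=["pos", "strand", "context"]))
    if not rows:
        return pd.DataFrame(columns=["pos", "strand", "context"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], ignore_index=True)


@dataclass
class BisulfiteRead:
    """One aligned bisulfite read as an ordered list of cytosine calls.

    ``calls`` holds ``(offset, context, methylated)`` triples with strictly
    increasing offsets relative to ``start`` (0-based).
    """

    chrom: str
    start: int
    strand: str
    calls: Sequence[tuple[int, str, bool]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        offs = [c[0] for c in self.calls]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("call offsets must be strictly increasing")


def is_conversion_failure(read: BisulfiteRead, max_consecutive: int = 3) -> bool:
    """True when the read has a run of more than ``max_consecutive``
    methylated CHH calls.

    The run is counted over the read's CHH calls in order; CG/CHG calls
    neither break nor extend it (incomplete conversion affects every
    cytosine, so intervening contexts should not rescue a read).
    """
    run = 0
    for _, context, methylated in read.calls:
        if context != "CHH":
            continue
        run = run + 1 if methylated else 0
        if run > max_consecutive:
            return True
    return False


def filter_conversion_failures(
    reads: Iterable[BisulfiteRead], max_consecutive: int = 3
) -> tuple[list[BisulfiteRead], int]:
    """Drop reads flagged by :func:`is_conversion_failure`.

    Returns (retained reads, number removed).  Idempotent: re-filtering a
    filtered stream removes nothing.
    """
    kept: list[BisulfiteRead] = []
    removed = 0
    for read in reads:
        if is_conversion_failure(read, max_consecutive):
            removed += 1
        else:
            kept.append(read)
    return kept, removed


@dataclass(frozen=True)
class CytosineLevel:
    level: float  # nan when total coverage is 0
    discarded: bool  # total coverage below the minimum


def cytosine_ratio(
    count_m: int, count_u: int, min_coverage: int = 0
) -> CytosineLevel:
    """Methylation level #C/(#C+#T) with a coverage gate.

    ``min_coverage=20`` reproduces the amplicon-sequencing rule (cytosines
    with less than 20 reads of coverage are discarded); whole-genome mode
    uses ``min_coverage=0``.
    """
    total = count_m + count_u
    if count_m < 0 or count_u < 0:
        raise ValueError("counts must be non-negative")
    level = math.nan if total == 0 else count_m / total
    return CytosineLevel(level=level, discarded=total < min_coverage)


def methylation_levels(
    records: pd.DataFrame, min_coverage: int = 0
) -> pd.DataFrame:
    """Vectorised :func:`cytosine_ratio` over a cytosine table.

    Adds ``level`` (nan at zero coverage) and ``discarded`` columns.
    """
    out = records.copy()
    total = out["count_m"] + out["count_u"]
    with np.errstate(invalid="ignore"):
        out["level"] = np.where(total > 0, out["count_m"] / total, np.nan)
    out["discarded"] = total < min_coverage
    return out


@dataclass(frozen=True)
class RegionMethylation:
    """Coverage-weighted methylation of one context over one interval."""

    interval: GenomicInterval
    context: str
    count_m: int
    total: int
    n_covered: int  # cytosines of the context with coverage > 0

    @property
    def level(self) -> float:
        """Sum(mC) / Sum(mC + uC); nan when nothing is covered."""
        return math.nan if self.total == 0 else self.count_m / self.total


def region_summary(
    records: pd.DataFrame, interval: GenomicInterval, context: str
) -> RegionMethylation:
    """Pool per-cytosine counts of ``context`` inside ``interval``.

    Coverage-weighted pooling (not a mean of ratios): the region level is
    Sum(mC)/Sum(mC+uC) over covered cytosines, matching the pooled-count
    differential test applied to windows downstream.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context: {context!r}")
    pos0 = records["pos"].to_numpy() - 1
    mask = (
        (records["chrom"].to_numpy() == interval.chrom)
        & (pos0 >= interval.start)
        & (pos0 < interval.end)
        & (records["context"].to_numpy() == context)
    )
    sub = records.loc[mask]
    total_per = sub["count_m"] + sub["count_u"]
    covered = total_per > 0
    return RegionMethylation(
        interval=interval,
        context=context,
        count_m=int(sub.loc[covered, "count_m"].sum()),
        total=int(total_per[covered].sum()),
        n_covered=int(covered.sum()),
    )


def combine_bspcr_regions(
    summaries: Iterable[RegionMethylation],
) -> dict[str, float]:
    """Pool amplicon region summaries into one per-context level.

    Counts are pooled across regions before taking the ratio, so a deeply
    covered region weighs more than a shallow one.  Contexts with zero
    pooled coverage map to nan.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one region summary")
    m: dict[str, int] = {}
    t: dict[str, int] = {}
    for s in summaries:
        m[s.context] = m.get(s.context, 0) + s.count_m
        t[s.context] = t.get(s.context, 0) + s.total
    return {
        ctx: (math.nan if t[ctx] == 0 else m[ctx] / t[ctx]) for ctx in m
    }
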