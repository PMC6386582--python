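"""Per-site classification: peak retention, Pol V recruitment, siRNA
production, the multilevel targeting funnel, motif scanning and metaplots.

The recruitment rule is deliberately inverted, following the ChIP analysis
it reproduces: a bound site is flagged *not* recruited when the ZF-fusion
ChIP signal exceeds the Pol V (NRPE1) ChIP signal by more than 4-fold at
FDR < 0.05; every other bound site counts as recruited.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, concat_matrices
from .diffcounts import differential_table, size_factors
from .dmr import Window

__all__ = [
    "retain_zf_peaks",
    "classify_polv",
    "classify_sirna",
    "build_funnel",
    "venn",
    "metaplot",
    "scan_motif",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _normalized_group_means(
    frames: Mapping[str, pd.DataFrame],
    group_a: str,
    group_b: str,
    normalization: str = "none",
) -> tuple[pd.Series, pd.Series, CountMatrix]:
    if group_b not in frames:
        raise ValueError(f"missing {group_b!r} counts")
    cm = concat_matrices([(frames[group_a], group_a), (frames[group_b], group_b)])
    if normalization == "none":
        norm = cm.counts.astype(float)
    elif normalization == "median_of_ratios":
        try:
            factors = size_factors(cm.counts)
        except ValueError:
            factors = size_factors(cm.counts, fallback_to_totals=True)
        norm = cm.counts / factors
    elif normalization == "totals":
        totals = cm.counts.sum(axis=0)
        norm = cm.counts / (totals / np.exp(np.mean(np.log(totals))))
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    return (
        norm[cm.group_samples(group_a)].mean(axis=1),
        norm[cm.group_samples(group_b)].mean(axis=1),
        cm,
    )


def retain_zf_peaks(
    peaks: Sequence[GenomicInterval],
    chip: Mapping[str, pd.DataFrame],
    fusion: str = "fusion",
    control: str = "control",
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    normalization: str = "none",
) -> pd.DataFrame:
    """Keep peaks whose fusion/control enrichment is strictly > ``min_fold``.

    ``chip`` maps antibody name -> counts DataFrame (peaks x replicates).
    Fold = (normalized fusion mean + pseudocount) / (normalized control
    mean + pseudocount).  The default ``normalization="none"`` treats the
    counts as already depth-normalized (sequencing-depth-matched
    libraries); median-of-ratios would cancel a genuine enrichment shared
    by every peak, since peaks — unlike the genome-wide background a real
    library-size normalization rests on — are all signal.  Returns a frame
    indexed by peak feature with ``fold`` and ``bound`` columns.
    """
    if control not in chip:
        raise ValueError("peak retention requires a control ChIP track")
    mean_f, mean_c, _ = _normalized_group_means(
        chip, fusion, control, normalization
    )
    fold = (mean_f + pseudocount) / (mean_c + pseudocount)
    out = pd.DataFrame({"fold": fold, "bound": fold > min_fold})
    out.index.name = "site"
    if len(peaks) and len(peaks) != len(out):
        raise ValueError("peak list and count features differ in length")
    return out


def classify_polv(
    chip: Mapping[str, pd.DataFrame],
    bound: pd.Series | None = None,
    fusion: str = "fusion",
    polv: str = "polv",
    min_fold: float = 4.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pol V recruitment flag per site.

    NOT recruited iff normalized fusion/PolV fold > ``min_fold`` AND BH
    q < ``fdr`` (exact test across sites); every other bound site is
    recruited.  ``bound`` (optional boolean Series) gates the output:
    unbound sites are never recruited.
    """
    for key in (fusion, polv):
        if key not in chip:
            raise ValueError(f"missing {key!r} ChIP counts")
    cm = concat_matrices([(chip[fusion], fusion), (chip[polv], polv)])
    table = differential_table(cm, group_a=fusion, group_b=polv)
    fold = 2.0 ** table["log2fc"]
    not_recruited = (fold > min_fold) & (table["q"] < fdr)
    recruited = ~not_recruited
    if bound is not None:
        recruited &= bound.reindex(table.index).fillna(False).astype(bool)
    out = pd.DataFrame(
        {
            "fusion_over_polv_fold": fold,
            "q": table["q"],
            "polv_recruited": recruited,
        }
    )
    out.index.name = "site"
    return out


def classify_sirna(
    bins: Sequence[Window],
    counts: CountMatrix,
    fusion: str = "fusion",
    control: str = "control",
    min_fold: float = 4.0,
    fdr: float = 0.05,
    min_bins: int = 1,
) -> pd.DataFrame:
    """24-nt siRNA production flag per site.

    Each 100-bp bin is tested fusion vs control; BH is computed jointly
    across all bins of all sites (a single test family).  A site produces
    siRNAs iff at least ``min_bins`` of its bins pass fold > ``min_fold``
    and q < ``fdr``.  Sites with no bins are flagged not-producing with a
    warning.
    """
    table = differential_table(counts, group_a=fusion, group_b=control)
    fold = 2.0 ** table["log2fc"].to_numpy()
    passing = (fold > min_fold) & (table["q"].to_numpy() < fdr)
    hits: dict[object, int] = {}
    best_q: dict[object, float] = {}
    all_sites: dict[object, None] = {}
    for w, ok, qv in zip(bins, passing, table["q"].to_numpy()):
        for sid in w.site_ids:
            all_sites.setdefault(sid, None)
            best_q[sid] = min(best_q.get(sid, 1.0), float(qv))
            if ok:
                hits[sid] = hits.get(sid, 0) + 1
    if not all_sites:
        warnings.warn("no bins supplied; no site can produce siRNAs", stacklevel=2)
    out = pd.DataFrame(
        {
            "n_significant_bins": [hits.get(s, 0) for s in all_sites],
            "best_q": [best_q[s] for s in all_sites],
            "sirna_producing": [hits.get(s, 0) >= min_bins for s in all_sites],
        },
        index=pd.Index(all_sites, name="site"),
    )
    return out


def build_funnel(
    classifications: pd.DataFrame, levels: Sequence[str]
) -> list[dict]:
    """Nested counts through ordered boolean flags.

    Level k counts sites satisfying flags 1..k jointly; each entry reports
    the count, the percentage of the previous level and the site IDs.
    Omitting a flag name (e.g. no Pol V stage) simply shortens the funnel.
    """
    for name in levels:
        if name not in classifications.columns:
            raise KeyError(f"unknown flag: {name!r}")
    mask = pd.Series(True, index=classifications.index)
    out: list[dict] = []
    prev = len(classifications)
    for name in levels:
        mask = mask & classifications[name].astype(bool)
        count = int(mask.sum())
        pct = 100.0 * count / prev if prev else 0.0
        out.append(
            {
                "level": name,
                "count": count,
                "pct_of_previous": pct,
                "site_ids": list(classifications.index[mask]),
            }
        )
        prev = count
    return out


def venn(a: set, b: set, c: set | None = None) -> dict[str, int]:
    """Exclusive region cardinalities of 2 or 3 sets (totals preserved)."""
    a, b = set(a), set(b)
    if c is None:
        return {
            "a_only": len(a - b),
            "b_only": len(b - a),
            "ab": len(a & b),
        }
    c = set(c)
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }


def metaplot(
    track: Mapping[str, np.ndarray],
    intervals: Sequence[GenomicInterval],
    n_bins: int = 50,
    flank: int = 1000,
    flank_bins: int = 10,
) -> dict:
    """Aggregate a per-bp signal over scaled intervals plus fixed flanks.

    Each interval body is scaled to ``n_bins`` near-equal slices; each
    flank is ``flank_bins`` fixed-width bins.  Minus-strand intervals are
    reversed so bin 0 is always the 5' flank.  Intervals extending outside
    the track are skipped with a warning.  Returns per-bin mean, standard
    error and the per-interval matrix.
    """
    total_bins = 2 * flank_bins + n_bins
    rows = []
    for iv in intervals:
        arr = track.get(iv.chrom)
        if arr is None or iv.start - flank < 0 or iv.end + flank > len(arr):
            warnings.warn(f"interval {iv} outside track; skipped", stacklevel=2)
            continue
        left = arr[iv.start - flank : iv.start]
        body = arr[iv.start : iv.end]
        right = arr[iv.end : iv.end + flank]
        prof = np.concatenate(
            [
                np.array([s.mean() for s in np.array_split(left, flank_bins)]),
                np.array([s.mean() for s in np.array_split(body, n_bins)]),
                np.array([s.mean() for s in np.array_split(right, flank_bins)]),
            ]
        )
        if iv.strand == "-":
            prof = prof[::-1]
        rows.append(prof)
    matrix = np.array(rows) if rows else np.empty((0, total_bins))
    mean = matrix.mean(axis=0) if len(rows) else np.full(total_bins, np.nan)
    se = (
        matrix.std(axis=0, ddof=1) / np.sqrt(len(rows))
        if len(rows) > 1
        else np.zeros(total_bins)
    )
    return {"mean": mean, "se": se, "matrix": matrix, "n": len(rows)}


def _has_motif(seq: str, motif: str, max_mismatch: int) -> bool:
    n, m = len(seq), len(motif)
    if m > n:
        return False
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    mot = np.frombuffer(motif.upper().encode("ascii"), dtype="S1")
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += arr[j : j + n - m + 1] != mot[j]
    return bool((mism <= max_mismatch).any())


def scan_motif(
    genome: Mapping[str, str],
    intervals: Sequence[GenomicInterval],
    motif: str,
    max_mismatch: int = 0,
) -> float:
    """Fraction of intervals containing ``motif`` on either strand.

    An interval counts once regardless of hit multiplicity; hits are exact
    up to ``max_mismatch`` substitutions.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif.upper()) - set("ACGT"):
        raise ValueError("motif alphabet must be {A, C, G, T}")
    if not intervals:
        return 0.0
    rc = motif.translate(_COMPLEMENT)[::-1]
    n_hit = 0
    for iv in intervals:
        seq = genome[iv.chrom][iv.start : iv.end]
        if _has_motif(seq, motif, max_mismatch) or _has_motif(seq, rc, max_mismatch):
            n_hit += 1
    return n_hit / len(intervals)
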