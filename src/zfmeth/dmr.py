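"""Anchored differential-methylation-region calling over binding-site flanks.

100-bp windows tile the 1-kb flanks of each zinc-finger binding site; each
window is tested per context (CG/CHG/CHH) with the pooled-count exact test;
hyper-methylated windows passing a context-specific difference threshold
and an FDR cut are merged within 200 bp, then combined across contexts.
Also: the pre-existing-CHH / tRNA filters, decile ranking of regions by
methylation difference, and the 10%-mCG heritability rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, interval_sort_key
from .diffcounts import bh_fdr, fisher_exact_two_sided
from .methylation import CONTEXTS, region_summary

__all__ = [
    "Window",
    "DMR",
    "DEFAULT_DIFF_THRESHOLDS",
    "window_flanks",
    "test_windows",
    "call_hyperdmrs",
    "merge_dmrs",
    "combine_contexts",
    "filter_preexisting_chh",
    "rank_deciles",
    "decile_report",
    "classify_heritable",
]

#: Absolute (fusion - control) methylation-difference thresholds realizing
#: the "stringent criteria" for hyper-DMR calling; configurable everywhere.
DEFAULT_DIFF_THRESHOLDS: dict[str, float] = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}


@dataclass(frozen=True)
class Window:
    """A test window with back-pointers to the sites whose flanks contain it."""

    chrom: str
    start: int
    end: int
    site_ids: tuple = ()

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class DMR:
    """A (merged) differentially methylated region.

    ``counts`` holds per-context pooled counts ``(m_fus, u_fus, m_ctl,
    u_ctl)`` so merged differences can be recomputed coverage-weighted.
    ``p``/``q`` are the minima over the merged member windows.
    """

    interval: GenomicInterval
    contexts: frozenset
    diff: dict = field(default_factory=dict)  # context -> fusion - control
    counts: dict = field(default_factory=dict)
    p: float = 1.0
    q: float = 1.0
    site_ids: tuple = ()


def window_flanks(
    sites: Sequence[GenomicInterval],
    flank: int = 1000,
    window: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Window]:
    """Tile ``[start - flank, end + flank)`` of every site with windows.

    Windows are anchored at each site's ``start - flank`` and truncated at
    chromosome edges (and at ``end + flank`` for the last, partial window).
    Identical windows arising from overlapping sites are emitted once with
    all back-pointers.
    """
    if flank <= 0 or window <= 0:
        raise ValueError("flank and window must be positive")
    seen: dict[tuple, list] = {}
    order: list[tuple] = []
    for site in sites:
        site_id = site.name if site.name is not None else (site.chrom, site.start)
        lo = site.start - flank
        hi = site.end + flank
        if chrom_sizes is not None:
            hi = min(hi, chrom_sizes[site.chrom])
        for w0 in range(lo, hi, window):
            s = max(0, w0)
            e = min(w0 + window, hi)
            if e <= s:
                continue
            key = (site.chrom, s, e)
            if key not in seen:
                seen[key] = []
                order.append(key)
            seen[key].append(site_id)
    return [
        Window(chrom, s, e, tuple(seen[(chrom, s, e)]))
        for (chrom, s, e) in sorted(order)
    ]


def _pooled_window_counts(
    records: pd.DataFrame, windows: Sequence[Window], context: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (mC, total, covered-cytosine count) via prefix sums."""
    m = np.zeros(len(windows), dtype=np.int64)
    t = np.zeros(len(windows), dtype=np.int64)
    n = np.zeros(len(windows), dtype=np.int64)
    sub = records[records["context"] == context]
    w_chrom = np.array([w.chrom for w in windows])
    w_start = np.array([w.start for w in windows])
    w_end = np.array([w.end for w in windows])
    for chrom, grp in sub.groupby("chrom", sort=False):
        sel = np.nonzero(w_chrom == chrom)[0]
        if sel.size == 0:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        cm = grp["count_m"].to_numpy()[order]
        cu = grp["count_u"].to_numpy()[order]
        tot = cm + cu
        covered = (tot > 0).astype(np.int64)
        cum_m = np.concatenate(([0], np.cumsum(cm)))
        cum_t = np.concatenate(([0], np.cumsum(tot)))
        cum_n = np.concatenate(([0], np.cumsum(covered)))
        i0 = np.searchsorted(pos0, w_start[sel], side="left")
        i1 = np.searchsorted(pos0, w_end[sel], side="left")
        m[sel] = cum_m[i1] - cum_m[i0]
        t[sel] = cum_t[i1] - cum_t[i0]
        n[sel] = cum_n[i1] - cum_n[i0]
    return m, t, n


def test_windows(
    windows: Sequence[Window],
    fusion: pd.DataFrame,
    control: pd.DataFrame,
    context: str,
    min_cytosines: int = 4,
) -> pd.DataFrame:
    """Pooled-count exact test of fusion vs control per window.

    Counts of ``context`` cytosines are pooled within each window per
    group; difference = ratio_fusion - ratio_control; p from the two-sided
    conditional exact test on the 2x2 (mC/uC x group) table.  Windows with
    fewer than ``min_cytosines`` covered cytosines in either group are
    skipped (absent from the output).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context: {context!r}")
    m_f, t_f, n_f = _pooled_window_counts(fusion, windows, context)
    m_c, t_c, n_c = _pooled_window_counts(control, windows, context)
    keep = (n_f >= min_cytosines) & (n_c >= min_cytosines)
    keep &= (t_f > 0) & (t_c > 0)
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        return pd.DataFrame(
            columns=[
                "window_index", "chrom", "start", "end",
                "m_fus", "u_fus", "m_ctl", "u_ctl",
                "n_fus", "n_ctl", "diff", "p",
            ]
        )
    diff = m_f[idx] / t_f[idx] - m_c[idx] / t_c[idx]
    p = fisher_exact_two_sided(
        m_f[idx], t_f[idx] - m_f[idx], m_c[idx], t_c[idx] - m_c[idx]
    )
    return pd.DataFrame(
        {
            "window_index": idx,
            "chrom": [windows[i].chrom for i in idx],
            "start": [windows[i].start for i in idx],
            "end": [windows[i].end for i in idx],
            "m_fus": m_f[idx],
            "u_fus": t_f[idx] - m_f[idx],
            "m_ctl": m_c[idx],
            "u_ctl": t_c[idx] - m_c[idx],
            "n_fus": n_f[idx],
            "n_ctl": n_c[idx],
            "diff": diff,
            "p": p,
        }
    )


def _merge_run(members: list[DMR]) -> DMR:
    """Union a maximal run of gap-adjacent DMRs, recomputing differences
    coverage-weighted from the pooled member counts (windows are disjoint)."""
    if len(members) == 1:
        return members[0]
    chrom = members[0].interval.chrom
    start = min(d.interval.start for d in members)
    end = max(d.interval.end for d in members)
    counts: dict[str, np.ndarray] = {}
    for d in members:
        for ctx, c in d.counts.items():
            counts[ctx] = counts.get(ctx, np.zeros(4, dtype=np.int64)) + np.asarray(c)
    diff = {}
    for ctx, (mf, uf, mc, uc) in counts.items():
        tf, tc = mf + uf, mc + uc
        if tf > 0 and tc > 0:
            diff[ctx] = mf / tf - mc / tc
    site_ids = tuple(dict.fromkeys(s for d in members for s in d.site_ids))
    return DMR(
        interval=GenomicInterval(chrom, start, end),
        contexts=frozenset().union(*(d.contexts for d in members)),
        diff=diff,
        counts={k: tuple(int(x) for x in v) for k, v in counts.items()},
        p=min(d.p for d in members),
        q=min(d.q for d in members),
        site_ids=site_ids,
    )


def merge_dmrs(dmrs: Iterable[DMR], max_gap: int = 200) -> list[DMR]:
    """Union DMRs whose gap (next.start - prev.end) is < ``max_gap``.

    Strict inequality ("within 200 bp"); order-independent and idempotent.
    Merged differences are recomputed from summed pooled counts; contexts
    are unioned.
    """
    items = sorted(dmrs, key=lambda d: interval_sort_key(d.interval))
    out: list[DMR] = []
    run: list[DMR] = []
    run_end = None
    for d in items:
        if run and d.interval.chrom == run[0].interval.chrom and (
            d.interval.start - run_end < max_gap
        ):
            run.append(d)
            run_end = max(run_end, d.interval.end)
        else:
            if run:
                out.append(_merge_run(run))
            run = [d]
            run_end = d.interval.end
    if run:
        out.append(_merge_run(run))
    return out


def call_hyperdmrs(
    tested: Mapping[str, pd.DataFrame],
    windows: Sequence[Window],
    thresholds: Mapping[str, float] | None = None,
    fdr: float = 0.01,
    max_gap: int = 200,
) -> dict[str, list[DMR]]:
    """Per-context hyper-DMR lists from tested windows.

    A window is retained when difference >= threshold[context], BH q < fdr
    (q computed across that context's tested windows) and difference > 0
    (hyper only); retained windows are then merged with the gap rule.
    ``tested`` maps context -> the output of :func:`test_windows`.
    """
    thresholds = dict(DEFAULT_DIFF_THRESHOLDS if thresholds is None else thresholds)
    unknown = set(tested) - set(CONTEXTS)
    if unknown:
        raise ValueError(f"unknown context(s): {sorted(unknown)}")
    out: dict[str, list[DMR]] = {}
    for ctx, table in tested.items():
        thr = thresholds[ctx]
        if len(table) == 0:
            out[ctx] = []
            continue
        q = bh_fdr(table["p"].to_numpy())
        keep = (
            (table["diff"].to_numpy() >= thr)
            & (q < fdr)
            & (table["diff"].to_numpy() > 0)
        )
        dmrs = []
        for row, qv in zip(table.loc[keep].itertuples(index=False), q[keep]):
            w = windows[row.window_index]
            dmrs.append(
                DMR(
                    interval=GenomicInterval(row.chrom, row.start, row.end),
                    contexts=frozenset({ctx}),
                    diff={ctx: float(row.diff)},
                    counts={
                        ctx: (int(row.m_fus), int(row.u_fus),
                              int(row.m_ctl), int(row.u_ctl))
                    },
                    p=float(row.p),
                    q=float(qv),
                    site_ids=w.site_ids,
                )
            )
        out[ctx] = merge_dmrs(dmrs, max_gap=max_gap)
    return out


def combine_contexts(
    per_context: Mapping[str, Sequence[DMR]], max_gap: int = 200
) -> list[DMR]:
    """Concatenate per-context hyper-DMRs and merge across contexts.

    Regions of different contexts closer than ``max_gap`` become one region
    whose contributing contexts are recorded.
    """
    flat = [d for dmrs in per_context.values() for d in dmrs]
    return merge_dmrs(flat, max_gap=max_gap)


def filter_preexisting_chh(
    dmrs: Sequence[DMR],
    baseline_records: pd.DataFrame,
    trna: Sequence[GenomicInterval] = (),
    max_baseline: float = 0.05,
) -> list[DMR]:
    """Drop DMRs with pre-existing CHH methylation or tRNA overlap.

    A DMR is removed when the control-genotype CHH weighted level over its
    interval exceeds ``max_baseline`` (strictly), when it overlaps any tRNA
    interval by >= 1 bp, or — conservatively, with a warning — when the
    baseline is undefined (no covered CHH cytosine).
    """
    kept: list[DMR] = []
    for d in dmrs:
        summ = region_summary(baseline_records, d.interval, "CHH")
        if summ.total == 0:
            warnings.warn(
                f"no CHH baseline coverage for {d.interval}; dropping DMR",
                stacklevel=2,
            )
            continue
        if summ.level > max_baseline:
            continue
        if any(d.interval.overlaps(t) for t in trna):
            continue
        kept.append(d)
    return kept


def rank_deciles(
    regions: Sequence[DMR] | Sequence[GenomicInterval],
    differences: Sequence[float],
    n_bins: int = 10,
) -> list[np.ndarray]:
    """Split regions into ``n_bins`` near-equal bins by descending difference.

    Bin 1 holds the largest differences; ties are broken by (chrom, start);
    bin sizes differ by at most one (the earliest bins take the extras).
    Fewer regions than bins yields fewer bins, with a warning.
    """
    if len(regions) == 0:
        raise ValueError("cannot rank an empty region list")
    if len(regions) != len(differences):
        raise ValueError("regions and differences length mismatch")
    if len(regions) < n_bins:
        warnings.warn(
            f"only {len(regions)} regions for {n_bins} bins; "
            "emitting one region per bin",
            stacklevel=2,
        )
        n_bins = len(regions)
    ivs = [r.interval if isinstance(r, DMR) else r for r in regions]
    keys = sorted(
        range(len(regions)),
        key=lambda i: (-differences[i], ivs[i].chrom, ivs[i].start),
    )
    return [np.asarray(b, dtype=int) for b in np.array_split(keys, n_bins)]


def decile_report(
    regions: Sequence[DMR],
    fusion: pd.DataFrame,
    segregant: pd.DataFrame,
    control: pd.DataFrame,
    context: str = "CG",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Decile table of region methylation for three groups.

    Regions are ranked by (fusion - control) weighted level in ``context``
    (decile 1 = largest difference).  Per bin the mean fusion-control and
    segregant-control differences and mean absolute levels are reported —
    the heritability readout: a region whose gain survives loss of the
    transgene keeps a high segregant level.
    """
    levels = {}
    for name, rec in (("fusion", fusion), ("segregant", segregant), ("control", control)):
        levels[name] = np.array(
            [region_summary(rec, d.interval, context).level for d in regions]
        )
    diffs = levels["fusion"] - levels["control"]
    diffs = np.where(np.isnan(diffs), -np.inf, diffs)
    bins = rank_deciles(regions, diffs, n_bins=n_bins)
    rows = []
    for i, members in enumerate(bins, start=1):
        rows.append(
            {
                "decile": i,
                "n": len(members),
                "mean_diff_fusion": np.nanmean(
                    levels["fusion"][members] - levels["control"][members]
                ),
                "mean_diff_segregant": np.nanmean(
                    levels["segregant"][members] - levels["control"][members]
                ),
                "mean_fusion": np.nanmean(levels["fusion"][members]),
                "mean_segregant": np.nanmean(levels["segregant"][members]),
                "mean_control": np.nanmean(levels["control"][members]),
                "members": tuple(int(m) for m in members),
            }
        )
    return pd.DataFrame(rows)


def classify_heritable(
    segregant_mcg: float, control_mcg: float, min_gain: float = 0.10
) -> bool | None:
    """Heritable iff the segregant keeps >= ``min_gain`` more CG methylation
    than control.  Returns None (not classifiable) when either level is
    undefined (nan)."""
    if np.isnan(segregant_mcg) or np.isnan(control_mcg):
        return None
    # tolerance keeps the >= boundary stable under float subtraction
    return bool(segregant_mcg - control_mcg >= min_gain - 1e-12)
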