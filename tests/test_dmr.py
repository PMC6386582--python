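"""Window tiling, window tests, hyper-DMR calling, merging, deciles."""

import numpy as np
import pandas as pd
import pytest

from zfmeth.core import GenomicInterval
from zfmeth.dmr import (
    DMR,
    call_hyperdmrs,
    classify_heritable,
    combine_contexts,
    filter_preexisting_chh,
    merge_dmrs,
    rank_deciles,
    test_windows as run_window_tests,
    window_flanks,
)


def iv(start, end, chrom="c", **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestWindowFlanks:
    def test_site_yields_contiguous_tiling(self):
        wins = window_flanks([iv(5000, 5200, name="s")], flank=1000, window=100)
        assert len(wins) == 22
        assert wins[0].start == 4000 and wins[-1].end == 6200
        # contiguity
        for a, b in zip(wins, wins[1:]):
            assert a.end == b.start

    def test_truncation_at_chromosome_start(self):
        wins = window_flanks([iv(30, 130, name="s")], flank=1000, window=100)
        assert wins[0].start == 0
        assert all(w.start >= 0 for w in wins)

    def test_truncation_at_chromosome_end(self):
        wins = window_flanks(
            [iv(900, 1000, name="s")], flank=1000, window=100,
            chrom_sizes={"c": 1500},
        )
        assert max(w.end for w in wins) == 1500

    def test_shared_windows_deduplicated_with_backpointers(self):
        sites = [iv(1000, 1200, name="s1"), iv(1000, 1200, name="s2")]
        wins = window_flanks(sites, flank=1000, window=100)
        assert len(wins) == 22
        assert all(w.site_ids == ("s1", "s2") for w in wins)

    @pytest.mark.parametrize("flank,window", [(0, 100), (1000, 0), (-5, 100)])
    def test_invalid_parameters(self, flank, window):
        with pytest.raises(ValueError):
            window_flanks([iv(0, 100)], flank=flank, window=window)

    def test_union_length_bounded_by_site_plus_flanks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            start = int(rng.integers(0, 5000))
            width = int(rng.integers(50, 700))
            site = iv(start, start + width, name="s")
            wins = window_flanks([site], flank=1000, window=100)
            covered = sum(w.end - w.start for w in wins)
            assert covered <= width + 2000
            assert min(w.start for w in wins) == max(0, start - 1000)


def records(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "count_m", "count_u"]
    )


def window_records(m, u, context="CG", n_cyt=5, start=0, chrom="c"):
    """n_cyt covered cytosines inside [start, start+100) summing to (m, u)."""
    rows = []
    mm = [m // n_cyt] * n_cyt
    mm[0] += m - sum(mm)
    uu = [u // n_cyt] * n_cyt
    uu[0] += u - sum(uu)
    for i in range(n_cyt):
        rows.append((chrom, start + 10 * i + 1, "+", context, mm[i], uu[i]))
    return records(rows)


class TestTestWindows:
    def test_strong_difference_small_p(self):
        wins = window_flanks([iv(0, 100, name="s")], flank=100, window=100)
        target = [w for w in wins if w.start == 0][0]
        fusion = window_records(40, 10)
        control = window_records(5, 45)
        out = run_window_tests([target], fusion, control, "CG")
        assert len(out) == 1
        assert out["diff"].iloc[0] == pytest.approx(40 / 50 - 5 / 50)
        assert out["p"].iloc[0] < 1e-10

    def test_identical_counts_null(self):
        w = window_flanks([iv(0, 100, name="s")], flank=100, window=100)[0]
        rec = window_records(10, 40)
        out = run_window_tests([w], rec, rec.copy(), "CG")
        assert out["diff"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_uncovered_window_skipped(self):
        w = window_flanks([iv(0, 100, name="s")], flank=100, window=100)[0]
        empty = records([])
        out = run_window_tests([w], empty, empty, "CG")
        assert len(out) == 0

    def test_min_cytosines_gate(self):
        w = window_flanks([iv(0, 100, name="s")], flank=100, window=100)[0]
        rec = window_records(10, 10, n_cyt=3)
        assert len(run_window_tests([w], rec, rec, "CG", min_cytosines=4)) == 0
        assert len(run_window_tests([w], rec, rec, "CG", min_cytosines=3)) == 1

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            run_window_tests([], records([]), records([]), "CGN")


def make_tested(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "window_index", "chrom", "start", "end",
            "m_fus", "u_fus", "m_ctl", "u_ctl", "n_fus", "n_ctl", "diff", "p",
        ],
    )


class TestCallHyperdmrs:
    def _windows(self, n=3):
        return window_flanks([iv(0, 100, name="s")], flank=100, window=100)[:n]

    def test_threshold_and_fdr_application(self):
        wins = self._windows()
        tested = {
            "CHH": make_tested(
                [
                    (0, "c", 0, 100, 12, 88, 0, 100, 5, 5, 0.12, 1e-6),
                    (1, "c", 100, 200, 8, 92, 0, 100, 5, 5, 0.08, 1e-6),
                    (2, "c", 200, 300, 30, 70, 40, 60, 5, 5, -0.10, 1e-6),
                ]
            )
        }
        out = call_hyperdmrs(tested, wins)
        starts = [d.interval.start for d in out["CHH"]]
        assert starts == [0]  # 0.12 >= 0.1 kept; 0.08 below; negative dropped

    def test_cg_just_below_threshold_dropped(self):
        wins = self._windows(1)
        tested = {
            "CG": make_tested([(0, "c", 0, 100, 39, 61, 0, 100, 5, 5, 0.39, 1e-9)])
        }
        assert call_hyperdmrs(tested, wins)["CG"] == []

    def test_fdr_gate(self):
        wins = self._windows(1)
        tested = {
            "CG": make_tested([(0, "c", 0, 100, 50, 50, 0, 100, 5, 5, 0.5, 0.5)])
        }
        assert call_hyperdmrs(tested, wins)["CG"] == []

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            call_hyperdmrs({"CGX": make_tested([])}, [])


def dmr(start, end, context="CG", m_f=50, u_f=50, m_c=5, u_c=95, chrom="c"):
    return DMR(
        interval=GenomicInterval(chrom, start, end),
        contexts=frozenset({context}),
        diff={context: m_f / (m_f + u_f) - m_c / (m_c + u_c)},
        counts={context: (m_f, u_f, m_c, u_c)},
        p=1e-8,
        q=1e-6,
    )


class TestMerging:
    def test_gap_150_merged(self):
        out = merge_dmrs([dmr(100, 200), dmr(350, 450)], max_gap=200)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 450)

    def test_gap_250_not_merged(self):
        out = merge_dmrs([dmr(100, 200), dmr(450, 550)], max_gap=200)
        assert len(out) == 2

    def test_gap_exactly_200_not_merged(self):
        out = merge_dmrs([dmr(100, 200), dmr(400, 500)], max_gap=200)
        assert len(out) == 2  # strict: gap < 200 merges

    def test_merged_difference_is_coverage_weighted(self):
        a = dmr(100, 200, m_f=90, u_f=10, m_c=10, u_c=90)
        b = dmr(250, 350, m_f=10, u_f=90, m_c=10, u_c=90)
        out = merge_dmrs([a, b], max_gap=200)
        assert out[0].diff["CG"] == pytest.approx(100 / 200 - 20 / 200)

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(6)
        dmrs = []
        for _ in range(30):
            s = int(rng.integers(0, 10_000))
            dmrs.append(dmr(s, s + int(rng.integers(50, 300))))
        once = merge_dmrs(dmrs)
        assert merge_dmrs(once) == merge_dmrs(once)
        shuffled = list(dmrs)
        rng.shuffle(shuffled)
        assert [d.interval for d in merge_dmrs(shuffled)] == [
            d.interval for d in once
        ]

    def test_output_pairwise_gaps_respect_max_gap(self):
        rng = np.random.default_rng(7)
        dmrs = [dmr(int(s), int(s) + 100) for s in rng.integers(0, 20_000, 50)]
        out = merge_dmrs(dmrs, max_gap=200)
        for a, b in zip(out, out[1:]):
            assert b.interval.start - a.interval.end >= 200

    def test_combine_contexts_unions_context_sets(self):
        out = combine_contexts(
            {"CG": [dmr(0, 100, "CG")], "CHH": [dmr(150, 250, "CHH")]}
        )
        assert len(out) == 1
        assert out[0].contexts == frozenset({"CG", "CHH"})
        assert (out[0].interval.start, out[0].interval.end) == (0, 250)

    def test_combine_contexts_disjoint(self):
        out = combine_contexts(
            {"CG": [dmr(0, 100, "CG")], "CHH": [dmr(400, 500, "CHH")]}
        )
        assert len(out) == 2

    def test_combine_contexts_empty(self):
        assert combine_contexts({"CG": [], "CHG": [], "CHH": []}) == []


class TestPreexistingChhFilter:
    def baseline(self, level, n=10):
        m = int(round(level * 100))
        rows = [("c", 10 * i + 1, "+", "CHH", m, 100 - m) for i in range(n)]
        return records(rows)

    def test_baseline_above_cutoff_removed(self):
        out = filter_preexisting_chh([dmr(0, 100)], self.baseline(0.06))
        assert out == []

    def test_baseline_below_cutoff_kept(self):
        d = dmr(0, 100)
        out = filter_preexisting_chh([d], self.baseline(0.04))
        assert out == [d]

    def test_trna_overlap_removed_despite_zero_baseline(self):
        out = filter_preexisting_chh(
            [dmr(0, 100)], self.baseline(0.0), trna=[iv(99, 150)]
        )
        assert out == []

    def test_missing_baseline_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no CHH baseline"):
            out = filter_preexisting_chh([dmr(0, 100)], records([]))
        assert out == []


class TestDeciles:
    def test_even_split(self):
        regions = [dmr(100 * i, 100 * i + 50) for i in range(20)]
        bins = rank_deciles(regions, np.linspace(1, 0, 20))
        assert [len(b) for b in bins] == [2] * 10

    def test_balanced_partition_23(self):
        regions = [dmr(100 * i, 100 * i + 50) for i in range(23)]
        bins = rank_deciles(regions, np.linspace(1, 0, 23))
        assert [len(b) for b in bins] == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_ordering_and_tie_rule(self):
        regions = [dmr(100 * i, 100 * i + 50) for i in range(10)]
        bins = rank_deciles(regions, [0.5] * 10)
        # all-equal differences: coordinate order, balanced bins
        assert [b[0] for b in bins] == list(range(10))

    def test_decile_one_has_largest_differences(self):
        rng = np.random.default_rng(9)
        diffs = rng.random(40)
        regions = [dmr(100 * i, 100 * i + 50) for i in range(40)]
        bins = rank_deciles(regions, diffs)
        means = [np.mean(diffs[b]) for b in bins]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_deciles([], [])

    def test_fewer_regions_than_bins_warns(self):
        regions = [dmr(0, 50), dmr(200, 250)]
        with pytest.warns(UserWarning):
            bins = rank_deciles(regions, [0.2, 0.1])
        assert len(bins) == 2


class TestHeritability:
    @pytest.mark.parametrize(
        "seg,ctl,expected",
        [
            (0.35, 0.20, True),  # gain 0.15 >= 0.10
            (0.25, 0.20, False),  # gain 0.05
            (0.10, 0.20, False),  # negative gain
            (0.30, 0.20, True),  # boundary: exactly 0.10 counts
        ],
    )
    def test_ten_percent_cg_rule(self, seg, ctl, expected):
        assert classify_heritable(seg, ctl) is expected

    def test_undefined_levels_not_classifiable(self):
        assert classify_heritable(float("nan"), 0.2) is None
        assert classify_heritable(0.2, float("nan")) is None
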