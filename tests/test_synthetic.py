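"""Generator determinism, truth nesting, planted effects and noise models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from zfmeth.methylation import BisulfiteRead, filter_conversion_failures
from zfmeth.sites import scan_motif
from zfmeth.synthetic import (
    SimulationConfig,
    consecutive_chh_removal_mask,
    generate_genome,
    simulate_bisulfite,
    simulate_chip_counts,
    simulate_expression,
    simulate_phenotypes,
    simulate_sirna_bins,
)
from conftest import small_sim_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_polv_recruited": 1.2},
            {"conversion_failure_rate": -0.1},
            {"motif": ""},
            {"motif": "ACGX"},
            {"nb_dispersion": 0.0},
            {"repression_fold": 0.5},
            {"replicates_per_group": 0},
            {"meth_baseline": {"CG": 0.6, "CHG": 0.03, "CHH": 0.02},
             "meth_gain": {"CG": 0.5, "CHG": 0.3, "CHH": 0.2}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_sim_config(**kw)

    def test_motif_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(chromosome_length=5, motif="ACGTACGTAC")


class TestGenerateGenome:
    def test_same_seed_identical_outputs(self, small_config):
        a = generate_genome(small_config)
        b = generate_genome(small_config)
        assert a.genome == b.genome
        assert a.sites == b.sites
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.gene_truth, b.gene_truth)

    def test_motif_planted_at_every_site(self, small_config, small_dataset):
        g = small_dataset.genome
        assert scan_motif(g.genome, g.sites, small_config.motif) == 1.0

    def test_degenerate_config_no_recruited_sites(self):
        g = generate_genome(small_sim_config(frac_polv_recruited=0.0))
        t = g.truth
        assert not t["is_polv_recruited"].any()
        assert not t["is_sirna_producing"].any()
        assert not t["is_hypermethylated"].any()

    def test_truth_nesting_holds(self):
        for seed in (1, 2, 3):
            t = generate_genome(small_sim_config(seed=seed)).truth
            assert (t["is_hypermethylated"] <= t["is_sirna_producing"]).all()
            assert (t["is_sirna_producing"] <= t["is_polv_recruited"]).all()
            assert (t["is_polv_recruited"] <= t["is_bound"]).all()

    def test_flag_counts_follow_binomial_law_over_seeds(self):
        """Pooled over 50 seeds, realized flag counts sit inside the 99%
        interval of the corresponding binomial (100/90/9/4.5 expected)."""
        cfg0 = SimulationConfig(
            n_chromosomes=1, chromosome_length=320_000, n_sites=100,
            frac_polv_recruited=0.9, frac_sirna_producing=0.1,
            frac_hypermethylated=0.5, n_genes=60,
        )
        totals = np.zeros(3, dtype=int)
        n_seeds = 50
        for seed in range(n_seeds):
            t = generate_genome(
                SimulationConfig(**{**cfg0.__dict__, "seed": seed})
            ).truth
            totals += np.array(
                [
                    t["is_polv_recruited"].sum(),
                    t["is_sirna_producing"].sum(),
                    t["is_hypermethylated"].sum(),
                ]
            )
        n = n_seeds * 100
        for total, p in zip(totals, (0.9, 0.09, 0.045)):
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= total <= hi

    def test_site_separation_prevents_flank_overlap(self, small_dataset):
        sites = sorted(
            small_dataset.genome.sites, key=lambda s: (s.chrom, s.start)
        )
        for a, b in zip(sites, sites[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end >= 2000

    def test_planted_genes_sit_downstream_of_hyper_sites(self, small_dataset):
        g = small_dataset.genome
        t = g.truth
        for sid in t.index[t["is_hypermethylated"]]:
            assert -200 <= t.loc[sid, "tss_distance"] <= 0


class TestChipCounts:
    def test_moment_oracle_realized_fold(self):
        cfg = small_sim_config(
            n_sites=200, chromosome_length=700_000, n_chromosomes=2,
            chip_enrichment_fold=8.0, replicates_per_group=3,
        )
        g = generate_genome(cfg)
        chip = simulate_chip_counts(g.truth, cfg)
        fusion = chip["fusion"].mean(axis=1)
        control = chip["control"].mean(axis=1)
        realized = fusion.mean() / control.mean()
        assert 6.0 <= realized <= 10.0  # within +/-25% of 8

    def test_nonrecruited_sites_lack_polv_signal(self, small_dataset):
        t = small_dataset.truth
        polv = small_dataset.chip["polv"].mean(axis=1)
        rec = polv[t["is_polv_recruited"]].mean()
        if (~t["is_polv_recruited"]).any():
            non = polv[~t["is_polv_recruited"]].mean()
            assert rec > 3 * non

    def test_unknown_antibody_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            simulate_chip_counts(
                small_dataset.truth, small_dataset.config, antibodies=("flag",)
            )


class TestBisulfite:
    def test_same_seed_bitwise_identical(self, small_config):
        g = generate_genome(small_config)
        a, _ = simulate_bisulfite(g.truth, g, small_config, groups=("control",))
        b, _ = simulate_bisulfite(g.truth, g, small_config, groups=("control",))
        pd.testing.assert_frame_equal(a["control"], b["control"])

    def test_zero_failure_rate_removes_almost_nothing(self):
        cfg = small_sim_config(conversion_failure_rate=0.0)
        g = generate_genome(cfg)
        tabs, removed = simulate_bisulfite(g.truth, g, cfg, groups=("control",))
        n_reads = int(
            round(cfg.coverage_mean * 2200 / cfg.read_length) * cfg.n_sites
        )
        # only chance runs of >3 methylated CHH at baseline 0.02 remain
        assert removed["control"] / n_reads < 0.01

    def test_failure_reads_are_filtered(self):
        cfg_hi = small_sim_config(conversion_failure_rate=0.05)
        g = generate_genome(cfg_hi)
        _, removed_hi = simulate_bisulfite(g.truth, g, cfg_hi, groups=("control",))
        cfg_lo = small_sim_config(conversion_failure_rate=0.0)
        _, removed_lo = simulate_bisulfite(g.truth, g, cfg_lo, groups=("control",))
        assert removed_hi["control"] > 10 * max(removed_lo["control"], 1)

    def test_planted_gain_visible_in_fusion_levels(self, small_dataset):
        t = small_dataset.truth
        hyper = t.index[t["is_hypermethylated"]]
        if len(hyper) == 0:
            pytest.skip("no hypermethylated site in this draw")
        from zfmeth.core import GenomicInterval
        from zfmeth.methylation import region_summary

        sid = hyper[0]
        row = t.loc[sid]
        iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        fus = region_summary(small_dataset.bisulfite["fusion"], iv, "CG")
        ctl = region_summary(small_dataset.bisulfite["control"], iv, "CG")
        assert fus.level - ctl.level > 0.3

    def test_heritable_sites_keep_cg_gain_in_segregant(self, small_dataset):
        t = small_dataset.truth
        from zfmeth.core import GenomicInterval
        from zfmeth.methylation import region_summary

        for sid in t.index[t["is_hypermethylated"]]:
            row = t.loc[sid]
            iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            seg = region_summary(small_dataset.bisulfite["segregant"], iv, "CG")
            ctl = region_summary(small_dataset.bisulfite["control"], iv, "CG")
            gain = seg.level - ctl.level
            if row["is_heritable"]:
                assert gain > 0.3
            else:
                assert abs(gain) < 0.15

    def test_baseline_plus_gain_above_one_rejected(self):
        with pytest.raises(ValueError):
            small_sim_config(
                meth_baseline={"CG": 0.6, "CHG": 0.03, "CHH": 0.02}
            )

    def test_vectorised_removal_mask_matches_object_filter(self):
        rng = np.random.default_rng(13)
        contexts = np.array(["CG", "CHG", "CHH"])
        for _ in range(20):
            n_reads = int(rng.integers(1, 12))
            read_ids, ctx_codes, meth, reads = [], [], [], []
            for r in range(n_reads):
                n_calls = int(rng.integers(0, 15))
                ctx = rng.integers(0, 3, size=n_calls)
                m = rng.random(n_calls) < 0.5
                read_ids.extend([r] * n_calls)
                ctx_codes.extend(ctx.tolist())
                meth.extend(m.tolist())
                reads.append(
                    BisulfiteRead(
                        "c", 0, "+",
                        tuple(
                            (i, contexts[c], bool(mm))
                            for i, (c, mm) in enumerate(zip(ctx, m))
                        ),
                    )
                )
            mask = consecutive_chh_removal_mask(
                np.array(read_ids, dtype=int),
                np.array(ctx_codes, dtype=np.int8),
                np.array(meth, dtype=bool),
                n_reads,
            )
            _, n_removed = filter_conversion_failures(reads)
            assert mask.sum() == n_removed


class TestSirnaBins:
    def test_channels_sum_to_total_reads(self, small_dataset):
        s = small_dataset.sirna
        summed = sum(cm.counts.sum(axis=0) for cm in s.counts.values())
        pd.testing.assert_series_equal(s.total_reads, summed)

    def test_producing_sites_have_elevated_24nt_bins(self, small_dataset):
        t = small_dataset.truth
        s = small_dataset.sirna
        cm = s.counts["24nt"]
        fus = cm.counts[cm.group_samples("fusion")].mean(axis=1)
        producing = set(t.index[t["is_sirna_producing"]])
        if not producing:
            pytest.skip("no producing site in this draw")
        hot = [
            i for i, w in enumerate(s.bins)
            if set(w.site_ids) & producing and fus.iloc[i] > 25
        ]
        assert hot  # at least one strongly elevated bin per planted fold 10

    def test_invalid_bin_width_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            simulate_sirna_bins(
                small_dataset.truth, small_dataset.genome,
                small_dataset.config, bin_width=0,
            )

    def test_21_22_channels_stay_at_background(self, small_dataset):
        s = small_dataset.sirna
        for channel in ("21nt", "22nt"):
            cm = s.counts[channel]
            fus = cm.counts[cm.group_samples("fusion")].to_numpy().mean()
            ctl = cm.counts[cm.group_samples("control")].to_numpy().mean()
            assert abs(fus - ctl) < 1.0


class TestExpressionAndPhenotypes:
    def test_repressed_genes_lower_in_fusion(self, small_dataset):
        cm = small_dataset.expression
        rep = small_dataset.genome.gene_truth["is_repressed"]
        if not rep.any():
            pytest.skip("no repressed gene in this draw")
        fus = cm.counts[cm.group_samples("fusion")].mean(axis=1)
        ctl = cm.counts[cm.group_samples("control")].mean(axis=1)
        ratio = (ctl[rep] + 1) / (fus[rep] + 1)
        assert (ratio > 2).all()

    def test_null_repression_fold_gives_no_de(self):
        from zfmeth.expression import call_de

        cfg = small_sim_config(repression_fold=1.0)
        g = generate_genome(cfg)
        cm, _ = simulate_expression(g, cfg)
        up, down, _ = call_de(cm, group_a="fusion", group_b="control")
        assert len(up) + len(down) <= 2

    def test_library_imbalance_does_not_create_calls(self):
        from zfmeth.expression import call_de

        cfg = small_sim_config(repression_fold=1.0)
        g = generate_genome(cfg)
        cm, _ = simulate_expression(g, cfg, library_scale={"fusion": 3.0})
        up, down, _ = call_de(cm, group_a="fusion", group_b="control")
        assert len(up) + len(down) <= 2

    def test_phenotypes_separate_by_group(self, small_config):
        pheno = simulate_phenotypes(small_config)
        fus = pheno.loc[pheno["group"] == "fusion", "leaves"]
        epi = pheno.loc[pheno["group"] == "epiallele", "leaves"]
        assert (fus <= 20).mean() > 0.9
        assert (epi > 20).all()
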