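"""End-to-end pipeline: simulate -> classify -> DMR -> funnel -> integrate.

``PipelineConfig`` collects every threshold the stages apply; defaults
encode the published cutoffs (peak fold > 2; Pol V non-recruitment fold
> 4 at FDR 0.05; siRNA bin fold > 4 at FDR 0.05; DE fold 2 at FDR 0.05;
DMR merging within 200 bp; 10% mCG heritability gain; 20-leaf early
flowering).  Every applied threshold is logged so a run can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import expression as expr_mod
from . import sites as sites_mod
from .dmr import DEFAULT_DIFF_THRESHOLDS
from .fileio import write_bed, write_dataset
from .synthetic import SimulationConfig, simulate_dataset, component_rng

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("zfmeth")


@dataclass
class PipelineConfig:
    """Flat, validated configuration for a full pipeline run."""

    seed: int = 42
    outdir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # ChIP
    peak_min_fold: float = 2.0
    polv_min_fold: float = 4.0
    polv_fdr: float = 0.05
    # small RNA
    sirna_min_fold: float = 4.0
    sirna_fdr: float = 0.05
    sirna_min_bins: int = 1
    # DMR
    dmr_flank: int = 1000
    dmr_window: int = 100
    dmr_min_cytosines: int = 4
    dmr_fdr: float = 0.01
    dmr_diff_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_DIFF_THRESHOLDS)
    )
    dmr_merge_gap: int = 200
    apply_chh_baseline_filter: bool = False
    chh_baseline_max: float = 0.05
    heritable_min_gain: float = 0.10
    # expression
    de_fold: float = 2.0
    de_fdr: float = 0.05
    link_max_distance: int = 2000
    enrichment_bin_width: int = 200
    n_permutations: int = 1000
    # phenotype
    flowering_threshold: int = 20

    def __post_init__(self) -> None:
        for name in ("polv_fdr", "sirna_fdr", "dmr_fdr", "de_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("peak_min_fold", "polv_min_fold", "sirna_min_fold", "de_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dmr_flank <= 0 or self.dmr_window <= 0:
            raise ValueError("dmr_flank and dmr_window must be positive")
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be positive")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(raw["simulation"]) - sim_known
            if sim_unknown:
                raise ValueError(
                    f"unknown simulation keys: {sorted(sim_unknown)}"
                )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: object
    classifications: pd.DataFrame
    funnel: list
    dmrs_by_context: dict
    dmrs_combined: list
    decile_table: pd.DataFrame | None
    heritable_fraction_overall: float | None
    heritable_fraction_decile1: float | None
    de_up: set
    de_down: set
    enrichment_down: object | None
    enrichment_up: object | None
    flowering: dict
    report: dict


def _log_threshold(name: str, value) -> None:
    logger.info("threshold %s = %r", name, value)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order on a freshly simulated dataset.

    Stages: simulate -> peak retention -> Pol V classification -> siRNA
    classification -> anchored DMR calling + context combination ->
    funnel -> heritability deciles -> differential expression +
    TSS-distance enrichment -> flowering.  Deterministic given
    (config, seed); integer outputs are bitwise reproducible.
    """
    cfg = config
    for f in dataclasses.fields(cfg):
        if f.name not in ("simulation", "outdir"):
            _log_threshold(f.name, getattr(cfg, f.name))
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    logger.info("simulating dataset (seed %d)", cfg.seed)
    ds = simulate_dataset(sim)
    g = ds.genome
    site_index = pd.Index([s.name for s in g.sites], name="site")

    # --- ChIP: binding and Pol V recruitment -------------------------------
    peaks = sites_mod.retain_zf_peaks(
        g.sites, ds.chip, min_fold=cfg.peak_min_fold
    )
    polv = sites_mod.classify_polv(
        ds.chip, bound=peaks["bound"],
        min_fold=cfg.polv_min_fold, fdr=cfg.polv_fdr,
    )

    # --- small RNA ----------------------------------------------------------
    sirna = sites_mod.classify_sirna(
        ds.sirna.bins, ds.sirna.counts["24nt"],
        min_fold=cfg.sirna_min_fold, fdr=cfg.sirna_fdr,
        min_bins=cfg.sirna_min_bins,
    ).reindex(site_index)
    sirna["sirna_producing"] = sirna["sirna_producing"].fillna(False).astype(bool)

    # --- anchored DMR calling ----------------------------------------------
    windows = dmr_mod.window_flanks(
        g.sites, flank=cfg.dmr_flank, window=cfg.dmr_window,
        chrom_sizes=g.chrom_sizes,
    )
    tested = {
        ctx: dmr_mod.test_windows(
            windows, ds.bisulfite["fusion"], ds.bisulfite["control"],
            ctx, min_cytosines=cfg.dmr_min_cytosines,
        )
        for ctx in ("CG", "CHG", "CHH")
    }
    per_context = dmr_mod.call_hyperdmrs(
        tested, windows, thresholds=cfg.dmr_diff_thresholds,
        fdr=cfg.dmr_fdr, max_gap=cfg.dmr_merge_gap,
    )
    combined = dmr_mod.combine_contexts(per_context, max_gap=cfg.dmr_merge_gap)
    if cfg.apply_chh_baseline_filter:
        combined = dmr_mod.filter_preexisting_chh(
            combined, ds.bisulfite["control"], g.trna,
            max_baseline=cfg.chh_baseline_max,
        )
    hyper_sites = {sid for d in combined for sid in d.site_ids}

    # --- per-site classification and funnel ---------------------------------
    classifications = pd.DataFrame(
        {
            "bound": peaks["bound"].reindex(site_index).to_numpy(),
            "polv_recruited": polv["polv_recruited"].reindex(site_index).to_numpy(),
            "sirna_producing": sirna["sirna_producing"].to_numpy(),
            "hyperdmr": [sid in hyper_sites for sid in site_index],
            "zf_fold": peaks["fold"].reindex(site_index).to_numpy(),
            "fusion_over_polv_fold": polv["fusion_over_polv_fold"]
            .reindex(site_index)
            .to_numpy(),
            "polv_q": polv["q"].reindex(site_index).to_numpy(),
            "sirna_best_q": sirna["best_q"].to_numpy(),
        },
        index=site_index,
    )
    funnel = sites_mod.build_funnel(
        classifications, ["bound", "polv_recruited", "sirna_producing", "hyperdmr"]
    )

    # --- heritability deciles ------------------------------------------------
    decile_table = None
    frac_overall = frac_decile1 = None
    if combined:
        decile_table = dmr_mod.decile_report(
            combined, ds.bisulfite["fusion"], ds.bisulfite["segregant"],
            ds.bisulfite["control"], context="CG",
        )
        heritable_flags = []
        for d in combined:
            seg = dmr_mod.region_summary(
                ds.bisulfite["segregant"], d.interval, "CG"
            ).level
            ctl = dmr_mod.region_summary(
                ds.bisulfite["control"], d.interval, "CG"
            ).level
            heritable_flags.append(
                dmr_mod.classify_heritable(seg, ctl, min_gain=cfg.heritable_min_gain)
            )
        flags = np.array([f for f in heritable_flags if f is not None], dtype=bool)
        frac_overall = float(flags.mean()) if flags.size else None
        d1 = decile_table.iloc[0]["members"]
        d1_flags = [heritable_flags[i] for i in d1 if heritable_flags[i] is not None]
        frac_decile1 = (
            float(np.mean(d1_flags)) if d1_flags else None
        )

    # --- expression integration ---------------------------------------------
    up, down, de_table = expr_mod.call_de(
        ds.expression, fold=cfg.de_fold, fdr=cfg.de_fdr,
        group_a="fusion", group_b="control",
    )
    gene_dist = expr_mod.nearest_dmr_distances(
        g.genes, combined, max_distance=cfg.link_max_distance
    )
    expressed = [gene.gene_id for gene in g.genes]
    enrich_down = enrich_up = None
    perm_seed = int(component_rng(cfg.seed, "perm").integers(2**31))
    if down:
        enrich_down = expr_mod.observed_expected(
            gene_dist, down, expressed,
            bin_width=cfg.enrichment_bin_width,
            max_distance=cfg.link_max_distance,
            n_perm=cfg.n_permutations, seed=perm_seed,
        )
    if up:
        enrich_up = expr_mod.observed_expected(
            gene_dist, up, expressed,
            bin_width=cfg.enrichment_bin_width,
            max_distance=cfg.link_max_distance,
            n_perm=cfg.n_permutations, seed=perm_seed + 1,
        )

    # proximal repressed gene per hyperdmr site
    link_table, _, _ = expr_mod.link_dmrs_to_genes(
        combined, g.genes, max_distance=cfg.link_max_distance,
        bin_width=cfg.enrichment_bin_width,
    ) if combined else (pd.DataFrame(columns=["dmr_index", "gene_id"]), None, None)
    proximal: dict[str, str] = {}
    for row in link_table.itertuples(index=False):
        if row.gene_id in down:
            for sid in combined[row.dmr_index].site_ids:
                proximal.setdefault(sid, row.gene_id)
    classifications["proximal_repressed_gene"] = [
        proximal.get(sid) for sid in site_index
    ]

    # --- phenotype -----------------------------------------------------------
    labels, flowering = expr_mod.classify_flowering(
        ds.phenotypes["leaves"].tolist(), threshold=cfg.flowering_threshold
    )
    flowering["by_group"] = {
        grp: sub["leaves"].le(cfg.flowering_threshold).mean()
        for grp, sub in ds.phenotypes.groupby("group")
    }

    report = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "funnel": [
            {k: v for k, v in lvl.items() if k != "site_ids"} for lvl in funnel
        ],
        "n_hyperdmrs_combined": len(combined),
        "n_hyperdmrs_per_context": {
            ctx: len(v) for ctx, v in per_context.items()
        },
        "heritable_fraction_overall": frac_overall,
        "heritable_fraction_decile1": frac_decile1,
        "n_de_up": len(up),
        "n_de_down": len(down),
        "flowering": {
            k: (dict(v) if isinstance(v, dict) else v) for k, v in flowering.items()
        },
    }
    if enrich_down is not None:
        report["enrichment_down_peak_bin"] = _peak_bin(enrich_down)

    result = PipelineResult(
        config=cfg, dataset=ds, classifications=classifications, funnel=funnel,
        dmrs_by_context=per_context, dmrs_combined=combined,
        decile_table=decile_table,
        heritable_fraction_overall=frac_overall,
        heritable_fraction_decile1=frac_decile1,
        de_up=up, de_down=down,
        enrichment_down=enrich_down, enrichment_up=enrich_up,
        flowering=flowering, report=report,
    )
    if cfg.outdir:
        _write_outputs(result)
    return result


def _peak_bin(curve) -> list[float] | None:
    ratio = curve.ratio
    if np.all(np.isnan(ratio)):
        return None
    i = int(np.nanargmax(ratio))
    return [float(curve.edges[i]), float(curve.edges[i + 1])]


def _write_outputs(result: PipelineResult) -> None:
    cfg = result.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash}
    write_dataset(result.dataset, out / "dataset")
    from .core import GenomicInterval

    write_bed(
        [
            GenomicInterval(
                d.interval.chrom, d.interval.start, d.interval.end,
                name="+".join(sorted(d.contexts)),
            )
            for d in result.dmrs_combined
        ],
        out / "hyperdmrs.bed",
    )
    result.classifications.to_csv(out / "site_classifications.tsv", sep="\t")
    if result.decile_table is not None:
        result.decile_table.drop(columns="members").to_csv(
            out / "deciles.tsv", sep="\t", index=False
        )
    if result.enrichment_down is not None:
        c = result.enrichment_down
        pd.DataFrame(
            {
                "bin_left": c.edges[:-1],
                "bin_right": c.edges[1:],
                "observed": c.observed,
                "expected": c.expected,
                "ratio": c.ratio,
            }
        ).to_csv(out / "enrichment_down.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump({**stamp, **result.report}, fh, indent=2, default=str)
    logger.info("wrote outputs to %s", out)
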