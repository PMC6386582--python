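"""Ground-truth simulator for zinc-finger-targeted RdDM analysis.

Generates a small multi-chromosome genome with planted motif-bearing
binding sites, nested site labels (bound > Pol V recruited > siRNA
producing > hypermethylated > heritable), negative-binomial ChIP and
small-RNA bin counts, read-level binomial bisulfite data with
conversion-failure reads, gene expression with TSS-proximity-coupled
repression, and flowering phenotypes.

All randomness flows from one seed through named per-component
sub-streams, so adding a component does not perturb the others and
identical (seed, config) pairs give bitwise-identical integer tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, concat_matrices
from .dmr import Window, window_flanks
from .expression import Gene
from .methylation import CONTEXTS, genome_cytosine_table

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedDataset",
    "component_rng",
    "generate_genome",
    "simulate_chip_counts",
    "simulate_bisulfite",
    "simulate_sirna_bins",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_dataset",
]

_CONTEXT_CODE = {c: i for i, c in enumerate(CONTEXTS)}


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Named sub-stream of the master seed (stable across sessions)."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng([int(seed), h])


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults encode the desk-scale reference conditions: 500 binding
    sites on a 4 x 500-kb genome, 90% Pol V recruitment, 10% siRNA
    production among recruited sites, 50% hypermethylation among
    producing sites with 60% heritability, 8-fold ChIP enrichment,
    10-fold planted siRNA gain, context gains CG 0.5 / CHG 0.3 / CHH 0.2
    at 30x bisulfite coverage, and 4-fold repression of genes whose TSS
    sits within 200 bp downstream of a planted methylated region.
    """

    seed: int = 42
    n_chromosomes: int = 4
    chromosome_length: int = 500_000
    gc_content: float = 0.36
    n_sites: int = 500
    site_width: int = 200
    min_site_separation: int = 2600
    motif: str = "TTGGTCCCAT"
    frac_polv_recruited: float = 0.9
    frac_sirna_producing: float = 0.1  # of recruited
    frac_hypermethylated: float = 0.5  # of producing
    frac_heritable: float = 0.6  # of hypermethylated
    chip_enrichment_fold: float = 8.0
    chip_background_mean: float = 50.0
    nb_dispersion: float = 0.05
    meth_baseline: dict = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.03, "CHH": 0.02}
    )
    meth_gain: dict = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.3, "CHH": 0.2}
    )
    gain_halo: int = 200  # methylation gain spreads this far beyond the site
    coverage_mean: float = 30.0
    read_length: int = 100
    conversion_failure_rate: float = 0.003
    sirna_fold: float = 10.0
    sirna_background_mean: float = 5.0
    n_genes: int = 300
    gene_length: int = 1500
    expression_mean: float = 100.0
    repression_fold: float = 4.0
    upstream_window: int = 200
    replicates_per_group: int = 2
    flank: int = 1000
    dmr_window: int = 100
    n_trna: int = 5
    trna_length: int = 80
    n_plants_per_group: int = 12

    def __post_init__(self) -> None:
        for name in (
            "frac_polv_recruited",
            "frac_sirna_producing",
            "frac_hypermethylated",
            "frac_heritable",
            "conversion_failure_rate",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_chromosomes", "chromosome_length", "n_sites", "site_width",
            "gene_length", "read_length", "flank", "dmr_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.motif or set(self.motif.upper()) - set("ACGT"):
            raise ValueError("motif must be non-empty over {A, C, G, T}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.chip_enrichment_fold <= 0 or self.sirna_fold <= 0:
            raise ValueError("enrichment folds must be positive")
        if self.repression_fold < 1:
            raise ValueError("repression_fold must be >= 1")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        for ctx in CONTEXTS:
            base, gain = self.meth_baseline[ctx], self.meth_gain[ctx]
            if not 0 <= base <= 1 or not 0 <= gain <= 1:
                raise ValueError("methylation proportions must lie in [0, 1]")
            if base + gain > 1:
                raise ValueError(
                    f"baseline + gain > 1 for {ctx}: {base} + {gain}"
                )
        if len(self.motif) > self.chromosome_length:
            raise ValueError("motif longer than the chromosome")


@dataclass
class SimulatedGenome:
    genome: dict
    sites: list  # GenomicInterval, named site_id
    genes: list  # Gene
    trna: list  # GenomicInterval
    truth: pd.DataFrame  # per-site flags + gains (+ nearest gene)
    gene_truth: pd.DataFrame  # per-gene repression flags

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size=None
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and var = mean + disp * mean^2."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    n = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size if size is not None else mean.shape)


def generate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Genome, planted sites, genes, tRNAs and the truth table.

    The motif is planted at every site summit; funnel flags are drawn
    Bernoulli per site (so realized counts fluctuate binomially across
    seeds) with the nesting hyper => siRNA => PolV => bound enforced by
    construction; heritable sites are a rounded ``frac_heritable`` subset
    of the hypermethylated ones.  One repressed gene is planted with its
    TSS 20-180 bp downstream of each hypermethylated site's gain region;
    remaining genes are placed uniformly without overlap on both strands.
    """
    cfg = config
    rng_seq = component_rng(cfg.seed, "genome")
    p = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
         cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
    )
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    genome_arr: dict[str, np.ndarray] = {}
    for i in range(cfg.n_chromosomes):
        draw = rng_seq.choice(4, size=cfg.chromosome_length, p=p)
        genome_arr[f"chr{i + 1}"] = bases[draw]

    # --- sites on a separation-respecting slot grid -----------------------
    # margin keeps flanks and any planted TSS-proximal gene inside the
    # chromosome
    margin = cfg.flank + cfg.site_width + cfg.gain_halo + 200 + cfg.gene_length
    slots = []
    for chrom in genome_arr:
        lo, hi = margin, cfg.chromosome_length - margin - cfg.site_width
        slots.extend(
            (chrom, int(s))
            for s in range(lo, hi, cfg.min_site_separation)
        )
    if len(slots) < cfg.n_sites:
        raise ValueError(
            f"genome too small for {cfg.n_sites} sites at separation "
            f"{cfg.min_site_separation} (capacity {len(slots)})"
        )
    rng_sites = component_rng(cfg.seed, "sites")
    chosen = sorted(rng_sites.choice(len(slots), size=cfg.n_sites, replace=False))
    sites: list[GenomicInterval] = []
    motif = np.frombuffer(cfg.motif.upper().encode(), dtype="S1")
    for k, slot_idx in enumerate(chosen):
        chrom, start = slots[slot_idx]
        summit = start + cfg.site_width // 2
        mstart = summit - len(motif) // 2
        genome_arr[chrom][mstart : mstart + len(motif)] = motif
        sites.append(
            GenomicInterval(
                chrom, start, start + cfg.site_width,
                name=f"site_{k:04d}", summit=summit,
            )
        )

    # --- nested truth flags ----------------------------------------------
    rng_truth = component_rng(cfg.seed, "truth")
    n = cfg.n_sites
    bound = np.ones(n, dtype=bool)
    polv = bound & (rng_truth.random(n) < cfg.frac_polv_recruited)
    sirna = polv & (rng_truth.random(n) < cfg.frac_sirna_producing)
    hyper = sirna & (rng_truth.random(n) < cfg.frac_hypermethylated)
    heritable = np.zeros(n, dtype=bool)
    hyper_idx = np.nonzero(hyper)[0]
    n_her = int(round(cfg.frac_heritable * hyper_idx.size))
    heritable[rng_truth.permutation(hyper_idx)[:n_her]] = True

    # --- genes -------------------------------------------------------------
    rng_genes = component_rng(cfg.seed, "genes")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_arr}
    for s in sites:  # keep random genes off the site gain regions
        occupied[s.chrom].append((s.start - cfg.gain_halo, s.end + cfg.gain_halo))
    genes: list[Gene] = []
    planted_gene_of_site: dict[str, str] = {}
    gid = 0
    for k in hyper_idx:
        site = sites[k]
        offset = int(rng_genes.integers(20, 181))
        if gid % 2 == 0:  # plus-strand gene downstream of the site
            tss = site.end + cfg.gain_halo + offset
            iv = GenomicInterval(site.chrom, tss, tss + cfg.gene_length, strand="+")
        else:  # minus-strand gene upstream of the site
            tss = site.start - cfg.gain_halo - offset
            iv = GenomicInterval(
                site.chrom, tss - cfg.gene_length + 1, tss + 1, strand="-"
            )
        gene = Gene(f"gene_{gid:04d}", iv, exon_length=cfg.gene_length)
        genes.append(gene)
        planted_gene_of_site[site.name] = gene.gene_id
        occupied[iv.chrom].append((iv.start, iv.end))
        gid += 1
    max_tries = 50 * cfg.n_genes
    tries = 0
    chroms = list(genome_arr)
    while gid < cfg.n_genes:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place genes without overlap")
        chrom = chroms[int(rng_genes.integers(len(chroms)))]
        start = int(rng_genes.integers(0, cfg.chromosome_length - cfg.gene_length))
        if any(start < e and s < start + cfg.gene_length for s, e in occupied[chrom]):
            continue
        strand = "+" if rng_genes.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, start + cfg.gene_length, strand=strand)
        genes.append(Gene(f"gene_{gid:04d}", iv, exon_length=cfg.gene_length))
        occupied[chrom].append((iv.start, iv.end))
        gid += 1

    # --- tRNA decoys away from site flanks ---------------------------------
    rng_trna = component_rng(cfg.seed, "trna")
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_arr}
    for s in sites:
        forbidden[s.chrom].append(
            (s.start - cfg.flank - cfg.dmr_window, s.end + cfg.flank + cfg.dmr_window)
        )
    trna: list[GenomicInterval] = []
    tries = 0
    while len(trna) < cfg.n_trna and tries < 10_000:
        tries += 1
        chrom = chroms[int(rng_trna.integers(len(chroms)))]
        start = int(rng_trna.integers(0, cfg.chromosome_length - cfg.trna_length))
        if any(start < e and s < start + cfg.trna_length for s, e in forbidden[chrom]):
            continue
        trna.append(
            GenomicInterval(
                chrom, start, start + cfg.trna_length, name=f"trna_{len(trna)}"
            )
        )

    # --- truth tables -------------------------------------------------------
    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arr.items()}
    gene_repressed = _repressed_genes(sites, hyper, genes, cfg)
    nearest_gene, site_tss_dist = _site_gene_distances(sites, genes, cfg)
    truth = pd.DataFrame(
        {
            "site_id": [s.name for s in sites],
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "is_bound": bound,
            "is_polv_recruited": polv,
            "is_sirna_producing": sirna,
            "is_hypermethylated": hyper,
            "is_heritable": heritable,
            "gain_CG": np.where(hyper, cfg.meth_gain["CG"], 0.0),
            "gain_CHG": np.where(hyper, cfg.meth_gain["CHG"], 0.0),
            "gain_CHH": np.where(hyper, cfg.meth_gain["CHH"], 0.0),
            "nearest_gene_id": nearest_gene,
            "tss_distance": site_tss_dist,
        }
    ).set_index("site_id", drop=False)
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "is_repressed": [gene_repressed[g.gene_id] for g in genes],
        }
    ).set_index("gene_id", drop=False)
    return SimulatedGenome(
        genome=genome, sites=sites, genes=genes, trna=trna,
        truth=truth, gene_truth=gene_truth,
    )


def _gain_region(site: GenomicInterval, cfg: SimulationConfig) -> GenomicInterval:
    return GenomicInterval(
        site.chrom, max(0, site.start - cfg.gain_halo), site.end + cfg.gain_halo
    )


def _repressed_genes(sites, hyper, genes, cfg) -> dict[str, bool]:
    """A gene is repressed iff a hypermethylated gain region lies within
    ``upstream_window`` bp upstream of (or overlapping) its TSS."""
    from .expression import tss_distance

    out = {}
    for g in genes:
        rep = False
        for k in np.nonzero(hyper)[0]:
            site = sites[k]
            if site.chrom != g.interval.chrom:
                continue
            d = tss_distance(_gain_region(site, cfg), g)
            if d is not None and -cfg.upstream_window <= d <= 0:
                rep = True
                break
        out[g.gene_id] = rep
    return out


def _site_gene_distances(sites, genes, cfg):
    from .expression import tss_distance

    nearest, dist = [], []
    for s in sites:
        best_g, best_d = None, None
        for g in genes:
            if g.interval.chrom != s.chrom:
                continue
            d = tss_distance(_gain_region(s, cfg), g)
            if best_d is None or abs(d) < abs(best_d):
                best_g, best_d = g.gene_id, d
        nearest.append(best_g)
        dist.append(best_d if best_d is not None else np.iinfo(np.int64).max)
    return nearest, dist


# ---------------------------------------------------------------------------
# ChIP counts
# ---------------------------------------------------------------------------

def simulate_chip_counts(
    truth: pd.DataFrame,
    config: SimulationConfig,
    antibodies: Sequence[str] = ("fusion", "polv", "control"),
) -> dict[str, pd.DataFrame]:
    """Negative-binomial ChIP counts per antibody over the sites.

    Means: control = background everywhere; fusion = fold x background at
    bound sites; Pol V = fold x background only at recruited sites, so a
    bound, non-recruited site shows fusion signal without Pol V signal.
    """
    cfg = config
    if cfg.replicates_per_group < 1:
        raise ValueError("need at least one replicate per antibody")
    rng = component_rng(cfg.seed, "chip")
    mu0 = cfg.chip_background_mean
    means = {
        "control": np.full(len(truth), mu0),
        "fusion": np.where(
            truth["is_bound"], cfg.chip_enrichment_fold * mu0, mu0
        ),
        "polv": np.where(
            truth["is_polv_recruited"], cfg.chip_enrichment_fold * mu0, mu0
        ),
    }
    out: dict[str, pd.DataFrame] = {}
    for ab in antibodies:
        if ab not in means:
            raise ValueError(f"unknown antibody: {ab!r}")
        cols = {}
        for r in range(cfg.replicates_per_group):
            cols[f"{ab}_rep{r + 1}"] = _nb_counts(rng, means[ab], cfg.nb_dispersion)
        out[ab] = pd.DataFrame(cols, index=truth.index)
    return out


# ---------------------------------------------------------------------------
# Bisulfite
# ---------------------------------------------------------------------------

def consecutive_chh_removal_mask(
    read_ids: np.ndarray,
    contexts: np.ndarray,
    methylated: np.ndarray,
    n_reads: int,
    max_consecutive: int = 3,
) -> np.ndarray:
    """Vectorised conversion-failure rule over flat per-call arrays.

    ``read_ids`` must be block-sorted (calls of a read contiguous and in
    position order).  Returns a boolean mask over reads: True = removed
    (contains a run of more than ``max_consecutive`` methylated CHH calls,
    counted over CHH calls only).  Array counterpart of
    :func:`zfmeth.methylation.is_conversion_failure`.
    """
    chh = contexts == _CONTEXT_CODE["CHH"]
    rid = read_ids[chh]
    meth = methylated[chh]
    removed = np.zeros(n_reads, dtype=bool)
    if rid.size == 0:
        return removed
    pos = np.arange(rid.size)
    boundary = np.empty(rid.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = rid[1:] != rid[:-1]
    # virtual breaker just before each read block; real breaker at each
    # unmethylated CHH call
    v = np.where(~meth, pos, np.where(boundary, pos - 1, -1))
    last_break = np.maximum.accumulate(v)
    run_len = np.where(meth, pos - last_break, 0)
    removed[np.unique(rid[run_len > max_consecutive])] = True
    return removed


def _region_cytosines(
    genome_tables: Mapping[str, pd.DataFrame], chrom: str, start: int, end: int
):
    """Positions (0-based), strand codes and context codes within a region."""
    tab = genome_tables[chrom]
    pos0 = tab["pos"].to_numpy() - 1
    i0, i1 = np.searchsorted(pos0, (start, end))
    sub = tab.iloc[i0:i1]
    ctx = np.array([_CONTEXT_CODE[c] for c in sub["context"]], dtype=np.int8)
    return pos0[i0:i1], sub["strand"].to_numpy(), ctx


def simulate_bisulfite(
    truth: pd.DataFrame,
    sim_genome: SimulatedGenome,
    config: SimulationConfig,
    groups: Sequence[str] = ("fusion", "segregant", "control"),
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Read-level bisulfite simulation over the site flank regions.

    Reads of ``read_length`` bp are placed uniformly to ``coverage_mean``
    depth over each site's flank region; per-cytosine calls are Bernoulli
    at the context baseline, plus the planted gain inside hypermethylated
    gain regions (fusion group; segregant keeps the CG gain at heritable
    sites only).  A ``conversion_failure_rate`` fraction of reads is fully
    methylated; the consecutive-CHH filter is applied before tabulation.

    Returns (cytosine tables per group, removed-read counts per group).
    Tables hold only cytosines with coverage > 0, in cytosine-report
    layout (1-based positions).
    """
    cfg = config
    for ctx in CONTEXTS:
        if cfg.meth_baseline[ctx] + cfg.meth_gain[ctx] > 1:
            raise ValueError("baseline + gain exceeds 1")
    genome_tables = {
        chrom: genome_cytosine_table(seq, chrom)
        for chrom, seq in sim_genome.genome.items()
    }
    base = np.array([cfg.meth_baseline[c] for c in CONTEXTS])
    gain = np.array([cfg.meth_gain[c] for c in CONTEXTS])
    cg_only_gain = np.array([cfg.meth_gain["CG"], 0.0, 0.0])

    tables: dict[str, pd.DataFrame] = {}
    removed_counts: dict[str, int] = {}
    sites = sim_genome.sites
    chrom_sizes = sim_genome.chrom_sizes
    for group in groups:
        rng = component_rng(cfg.seed, f"bisulfite:{group}")
        rows: list[pd.DataFrame] = []
        n_removed = 0
        for site in sites:
            t = truth.loc[site.name]
            start = max(0, site.start - cfg.flank)
            end = min(chrom_sizes[site.chrom], site.end + cfg.flank)
            pos0, strands, ctx = _region_cytosines(
                genome_tables, site.chrom, start, end
            )
            if pos0.size == 0:
                continue
            level = base[ctx].copy()
            if group == "fusion" and t["is_hypermethylated"]:
                g = _gain_region(site, cfg)
                in_gain = (pos0 >= g.start) & (pos0 < g.end)
                level[in_gain] += gain[ctx[in_gain]]
            elif group == "segregant" and t["is_heritable"]:
                g = _gain_region(site, cfg)
                in_gain = (pos0 >= g.start) & (pos0 < g.end)
                level[in_gain] += cg_only_gain[ctx[in_gain]]

            n_reads = int(round(cfg.coverage_mean * (end - start) / cfg.read_length))
            if n_reads == 0 or end - start <= cfg.read_length:
                continue
            starts = rng.integers(start, end - cfg.read_length, size=n_reads)
            starts.sort()
            failure = rng.random(n_reads) < cfg.conversion_failure_rate
            lo = np.searchsorted(pos0, starts)
            hi = np.searchsorted(pos0, starts + cfg.read_length)
            lengths = hi - lo
            total = int(lengths.sum())
            if total == 0:
                continue
            read_idx = np.repeat(np.arange(n_reads), lengths)
            offsets = np.arange(total) - np.repeat(
                np.cumsum(lengths) - lengths, lengths
            )
            cyt_idx = np.repeat(lo, lengths) + offsets
            meth = rng.random(total) < level[cyt_idx]
            meth |= failure[read_idx]
            removed = consecutive_chh_removal_mask(
                read_idx, ctx[cyt_idx], meth, n_reads
            )
            n_removed += int(removed.sum())
            keep = ~removed[read_idx]
            m = np.bincount(
                cyt_idx[keep & meth], minlength=pos0.size
            )
            tot = np.bincount(cyt_idx[keep], minlength=pos0.size)
            covered = tot > 0
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": site.chrom,
                        "pos": pos0[covered] + 1,
                        "strand": strands[covered],
                        "context": np.array(CONTEXTS)[ctx[covered]],
                        "count_m": m[covered],
                        "count_u": tot[covered] - m[covered],
                    }
                )
            )
        if rows:
            tab = pd.concat(rows, ignore_index=True)
            # overlapping flank regions may duplicate cytosines; keep one draw
            tab = tab.drop_duplicates(
                subset=["chrom", "pos", "strand"], keep="first", ignore_index=True
            )
        else:
            tab = pd.DataFrame(
                columns=["chrom", "pos", "strand", "context", "count_m", "count_u"]
            )
        tables[group] = tab
        removed_counts[group] = n_removed
    return tables, removed_counts


# ---------------------------------------------------------------------------
# Small-RNA bins
# ---------------------------------------------------------------------------

@dataclass
class SirnaData:
    bins: list  # Window, with site back-pointers
    counts: dict  # size class ("24nt", "21nt", "22nt") -> CountMatrix
    total_reads: pd.Series  # per-sample totals across bins and size classes


def simulate_sirna_bins(
    truth: pd.DataFrame,
    sim_genome: SimulatedGenome,
    config: SimulationConfig,
    bin_width: int | None = None,
) -> SirnaData:
    """Negative-binomial small-RNA counts over 100-bp flank bins.

    The 24-nt channel carries the planted ``sirna_fold`` gain over bins
    overlapping a producing site's gain region in the fusion group; 21-
    and 22-nt channels stay at background (the gain is specific to the
    canonical RdDM size class).
    """
    cfg = config
    bw = cfg.dmr_window if bin_width is None else bin_width
    if bw <= 0:
        raise ValueError("bin width must be positive")
    bins = window_flanks(
        sim_genome.sites, flank=cfg.flank, window=bw,
        chrom_sizes=sim_genome.chrom_sizes,
    )
    rng = component_rng(cfg.seed, "sirna")
    producing = {
        s.name: bool(truth.loc[s.name, "is_sirna_producing"])
        for s in sim_genome.sites
    }
    gain_regions = {
        s.name: _gain_region(s, cfg) for s in sim_genome.sites
    }
    mu0 = cfg.sirna_background_mean
    base_mean = np.full(len(bins), mu0)
    fusion24 = base_mean.copy()
    for i, w in enumerate(bins):
        for sid in w.site_ids:
            g = gain_regions[sid]
            if producing[sid] and w.start < g.end and g.start < w.end:
                fusion24[i] = mu0 * cfg.sirna_fold
                break
    index = pd.Index([f"{w.chrom}:{w.start}-{w.end}" for w in bins], name="bin")
    counts: dict[str, CountMatrix] = {}
    reps = cfg.replicates_per_group
    totals = None
    for channel in ("24nt", "21nt", "22nt"):
        frames = []
        for group in ("fusion", "control"):
            mean = fusion24 if (channel == "24nt" and group == "fusion") else base_mean
            cols = {
                f"{group}_rep{r + 1}": _nb_counts(rng, mean, cfg.nb_dispersion)
                for r in range(reps)
            }
            frames.append((pd.DataFrame(cols, index=index), group))
        cm = concat_matrices(frames)
        counts[channel] = cm
        s = cm.counts.sum(axis=0)
        totals = s if totals is None else totals + s
    return SirnaData(bins=bins, counts=counts, total_reads=totals)


# ---------------------------------------------------------------------------
# Expression and phenotypes
# ---------------------------------------------------------------------------

def simulate_expression(
    sim_genome: SimulatedGenome,
    config: SimulationConfig,
    library_scale: Mapping[str, float] | None = None,
) -> tuple[CountMatrix, pd.Series]:
    """Gene expression counts with TSS-proximity-coupled repression.

    Genes flagged repressed in the gene truth (a hypermethylated gain
    region within ``upstream_window`` bp upstream of the TSS) have their
    fusion-group mean divided by ``repression_fold``.  ``library_scale``
    multiplies a group's means to emulate library-size imbalance.
    Returns (CountMatrix, per-gene exon lengths).
    """
    cfg = config
    if cfg.repression_fold < 1:
        raise ValueError("repression_fold must be >= 1")
    rng = component_rng(cfg.seed, "expression")
    genes = sim_genome.genes
    repressed = sim_genome.gene_truth["is_repressed"].to_numpy()
    mu = np.full(len(genes), cfg.expression_mean)
    frames = []
    index = pd.Index([g.gene_id for g in genes], name="gene_id")
    for group in ("fusion", "control"):
        mean = mu / cfg.repression_fold if group == "fusion" else mu
        mean = np.where(repressed, mean, mu)
        scale = (library_scale or {}).get(group, 1.0)
        cols = {
            f"{group}_rep{r + 1}": _nb_counts(rng, mean * scale, cfg.nb_dispersion)
            for r in range(cfg.replicates_per_group)
        }
        frames.append((pd.DataFrame(cols, index=index), group))
    cm = concat_matrices(frames)
    exon_lengths = pd.Series([g.exon_length for g in genes], index=index)
    return cm, exon_lengths


def simulate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Leaf counts at flowering: fusion plants early (silenced epiallele
    re-methylated), untransformed epiallele plants late."""
    cfg = config
    rng = component_rng(cfg.seed, "phenotype")
    n = cfg.n_plants_per_group
    fusion = np.clip(np.round(rng.normal(14, 2, size=n)), 5, None).astype(int)
    control = np.clip(np.round(rng.normal(28, 3, size=n)), 21, None).astype(int)
    return pd.DataFrame(
        {
            "plant": [f"fusion_{i}" for i in range(n)]
            + [f"epiallele_{i}" for i in range(n)],
            "group": ["fusion"] * n + ["epiallele"] * n,
            "leaves": np.concatenate([fusion, control]),
        }
    )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SimulatedGenome
    chip: dict  # antibody -> counts DataFrame
    bisulfite: dict  # group -> cytosine table
    bisulfite_removed: dict  # group -> removed-read count
    sirna: SirnaData
    expression: CountMatrix
    exon_lengths: pd.Series
    phenotypes: pd.DataFrame

    @property
    def truth(self) -> pd.DataFrame:
        return self.genome.truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every simulator component under one seed."""
    g = generate_genome(config)
    chip = simulate_chip_counts(g.truth, config)
    bis, removed = simulate_bisulfite(g.truth, g, config)
    sirna = simulate_sirna_bins(g.truth, g, config)
    expr, exon_lengths = simulate_expression(g, config)
    pheno = simulate_phenotypes(config)
    return SimulatedDataset(
        config=config, genome=g, chip=chip, bisulfite=bis,
        bisulfite_removed=removed, sirna=sirna, expression=expr,
        exon_lengths=exon_lengths, phenotypes=pheno,
    )
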