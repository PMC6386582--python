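# Methods

This note documents the statistical models, default parameters, design
choices and limitations of `zfmeth`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and data conventions

All in-memory intervals are 0-based half-open; GFF3 (1-based inclusive)
and cytosine reports (1-based positions) are converted only at file
boundaries (`fileio`).  Cytosine tables carry
`chrom, pos, strand, context, count_m, count_u`; counts are raw read
counts after conversion-failure filtering.

## Methylation quantification

A cytosine's context is read 5′→3′ on its own strand from the two
downstream bases: `CG`, `CHG`, `CHH` (H = A, T or C).  Positions within
2 bp of the 3′ chromosome end resolve only when the available bases
suffice (a downstream G fixes `CG`); otherwise the context is undefined
and the position is excluded.

**Conversion-failure filter.** Bisulfite non-conversion leaves a read
fully methylated; its signature is a long run of methylated CHH calls
(CHH methylation is sparse in genuine data).  A read is removed when it
contains more than 3 consecutive methylated CHH calls, counted over the
read's CHH calls in order.  Intervening CG/CHG calls neither break nor
extend the run: non-conversion affects every cytosine of the read, so an
interleaved methylated CG is evidence for, not against, failure.  The
filter is idempotent.

**Levels.** Per-cytosine level = `mC/(mC+uC)`; undefined at zero
coverage.  Amplicon (BS-PCR) mode discards cytosines with coverage
below 20; whole-genome mode applies no per-cytosine floor.  Region
levels use coverage-weighted pooling — `Σ mC / Σ(mC+uC)` over covered
cytosines of one context — rather than a mean of ratios, matching the
pooled-count window test and remaining stable at low coverage.  Amplicon
regions are combined by pooling counts across regions before the ratio.

## The shared two-group count test

The recruitment, siRNA and expression callers in the source analyses use
packaged negative-binomial tests.  This package substitutes a
deterministic conditional exact test: for each feature, the 2×2 table of
(summed raw counts in group A, group B) × (feature, library remainder)
is tested two-sided (Fisher); the two-sided p-value is the total
hypergeometric probability of tables with the observed margins whose
point probability does not exceed the observed one (relative tolerance
1e−7, as in R).  Rationale: fully specifiable, verifiable against exact
enumeration, conservative at the problem sizes exercised here, and free
of fitted hyperparameters.  A `test_hook` on `differential_table`
accepts an alternative per-feature test.  The vectorised implementation
evaluates one log-pmf per table and fills the support by the
hypergeometric ratio recurrence; tests pin it to `scipy.stats.
fisher_exact` and to full enumeration.

Pooling replicates discards between-replicate dispersion, so p-values
are anti-conservative for genuinely overdispersed features; the fold
threshold applied alongside FDR in every caller is what keeps observed
false discovery in check (measured on simulated truth by the acceptance
script).  This is the main caveat when moving from simulated to real
libraries.

Normalization is median-of-ratios over features positive in all samples
(factors rescaled to geometric mean 1), with a total-count fallback and
a unit-factor fallback for degenerate matrices.  Fold changes are
`log2((mean_A + 1)/(mean_B + 1))` on normalized means; the pseudocount
avoids infinities at zero counts.  FDR control is Benjamini–Hochberg
step-up (via statsmodels), verified against brute-force rejection sets.

One exception: ZF peak retention (fusion vs control fold > 2) uses raw
count means by default.  Median-of-ratios assumes most features are
null; peak features are all signal, so that normalization would cancel a
uniform enrichment.  Real analyses normalize by genome-wide library
depth; the simulator emits depth-matched libraries, for which unit
factors are the faithful equivalent.  `normalization=` exposes the
alternatives.  The Pol V classifier (fusion ChIP vs Pol V ChIP across
sites) keeps median-of-ratios because ~90% of sites are null for that
contrast.

## Anchored DMR calling

Windows of 100 bp tile `[start − 1000, end + 1000)` of every site,
anchored at each site's own `start − flank` and truncated at chromosome
edges; identical windows from overlapping sites are emitted once with
all site back-pointers.  Windows from *distinct* anchors are assumed
disjoint when merged regions recompute pooled counts; the simulator
enforces a minimum site separation (2,600 bp) that guarantees this.

Per context, pooled window counts are tested fusion vs control
(difference = ratio difference; p from the exact test); windows with
fewer than 4 covered cytosines in either group are skipped.  Hyper-DMRs
require difference ≥ threshold (CG 0.4, CHG 0.2, CHH 0.1), BH q < 0.01
across that context's tested windows, and difference > 0.  The source
procedure defers its criteria to a cited lineage; these defaults realize
its "stringent criteria" and are fully configurable.  Hypo-methylation
calling is not implemented; the analyses consume hyper-DMRs only.

Merging unions regions whose gap is strictly < 200 bp ("within 200 bp"
read as strict; the same rule combines contexts, where the wording
"less than 200 bp" is unambiguous).  Merged differences are recomputed
coverage-weighted from summed pooled counts; contexts are unioned; p and
q of a merged region are the minima over members.  Merging is
order-independent and idempotent.

The high-confidence CHH filter drops regions whose control CHH weighted
level exceeds 0.05, regions overlapping a tRNA interval by ≥ 1 bp, and —
conservatively, with a warning — regions with no CHH baseline coverage.

**Deciles and heritability.** Regions sort by (fusion − control)
difference, ties by (chrom, start), into 10 near-equal bins (earliest
bins take the extras, matching `np.array_split`).  A region is heritable
when segregant mCG − control mCG ≥ 0.10; the comparison carries a 1e−12
tolerance so the boundary survives float subtraction.  Undefined levels
make a region unclassifiable (excluded from the denominator).

## Site classification

Threshold semantics follow the stated rules exactly: fold thresholds are
strict (`> 2`, `> 4`), FDR thresholds strict (`< 0.05`), with a
pseudocount of 1 on normalized means.  The recruitment rule is
deliberately inverted: *non*-recruited sites are those with > 4-fold
fusion-over-PolV enrichment at q < 0.05; everything else bound is
recruited.  A site produces siRNAs when ≥ 1 of its bins passes (the
bin→site aggregation is unstated in the source; `min_bins` exposes a
stricter alternative).  BH for bins runs jointly across all bins of all
sites — a single test family, avoiding site-level selection bias.

The funnel counts sites satisfying the flag prefix jointly; levels can
be omitted (a Pol IV-arm funnel has no Pol V stage).  Metaplots scale
interval bodies to `n_bins` near-equal slices plus fixed-width flank
bins, reversing minus-strand intervals.  Motif scanning is a brute-force
both-strand Hamming scan; an interval counts once however many hits.

## Expression integration

RPKM = count / (exon kb) / (library millions).  DE calls use the shared
test at 2-fold / FDR 0.05, strict on both.  DMR→TSS distances are
signed: negative upstream in the gene's orientation, 0 on overlap,
measured from the nearer interval boundary (half-open convention; the
upstream side measures from the exclusive end, so reflection symmetry
holds on boundaries, not points).  Nearest-TSS ties go to the
smaller-coordinate gene.

**Observed/expected enrichment.** The cited distance-enrichment
algorithm is not specified in the source; expected counts here are the
mean over `n_perm` (default 1,000) uniform draws of `|DE set|` genes
without replacement from the expressed genes — a label permutation
preserving the gene count, of unknown fidelity to the original.  Bins
are right-closed, 200 bp wide over ±2 kb by default (the source plots
use sub-kilobase bins of unstated width; 200 bp aligns the proximal bin
with the 200-bp-upstream window the repression analysis emphasizes).
Ratios are undefined where expected = 0.  A `sampler` hook makes the
permutation identity for exactness tests.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with one seed feeding named per-component sub-streams
(`component_rng(seed, name)`), so outputs are bitwise reproducible and
adding a component never perturbs another.

Defaults (the reference conditions): 4 chromosomes × 500 kb at GC 0.36;
500 motif-bearing sites of 200 bp on a 2,600-bp separation grid (margins
keep flanks and planted genes inside chromosomes); nested Bernoulli
labels — 90% Pol V-recruited, 10% of those siRNA-producing, 50% of those
hypermethylated — and a deterministic rounded 60% of hypermethylated
sites heritable (an exact planted fraction, so the recovery target is
sharp; the Bernoulli funnel labels, by contrast, fluctuate binomially
across seeds, and a 50-seed test checks exactly that).

* **ChIP**: negative-binomial counts (variance = μ + αμ², shared
  dispersion α = 0.05, background mean 50); fusion mean ×8 at bound
  sites, Pol V mean ×8 only at recruited sites.  The source gives no
  dispersions; these are free parameters of the artifact.
* **Bisulfite**: read-level simulation over the site flank regions (the
  only regions any window interrogates): 100-bp reads placed uniformly
  to 30× mean coverage; per-cytosine Bernoulli calls at context
  baselines CG 0.05 / CHG 0.03 / CHH 0.02 (an unmethylated-region
  profile, consistent with the < 0.05 pre-existing-CHH site filter),
  plus gains CG 0.5 / CHG 0.3 / CHH 0.2 inside a hypermethylated site ±
  a 200-bp halo (methylation spreads locally beyond the bound site; the
  halo keeps the planted region well inside the tested flank).
  Segregants keep only the CG gain, only at heritable sites.  A 0.003
  fraction of reads is fully methylated (conversion failure) and the
  consecutive-CHH filter is applied before tabulation — the vectorised
  filter is pinned to the read-object implementation by test.
* **siRNA**: NB counts over the same 100-bp flank bins used downstream;
  the 24-nt channel carries a ×10 gain over bins overlapping a producing
  site's gain region in the fusion group; 21/22-nt channels stay at
  background (background mean 5/bin).  Channel totals are accounted so
  conservation is checkable.
* **Expression**: NB counts (mean 100) over uniformly placed
  non-overlapping genes (1.5 kb, both strands); one gene is planted per
  hypermethylated site with its TSS 20–180 bp downstream of the gain
  region (alternating strands), and any gene whose TSS has a gain region
  within 200 bp upstream is repressed ×4 in the fusion group.
  `library_scale` emulates depth imbalance for normalization tests.
* **Phenotypes**: leaf counts ≈ N(14, 2) for fusion plants (early,
  silencing restored) and ≥ 21 (≈ N(28, 3)) for unmethylated-epiallele
  controls.

What the simulator does **not** emulate: alignment artifacts, PCR
duplicates, mappability, copy-number or chromatin structure, locus-to-
locus variation in enrichment/dispersion/baseline, partial heritability,
or correlated noise between assays.  Passing recovery tests therefore
demonstrates the pipeline's correctness and calibration under its own
model assumptions, not performance on real libraries.

## Problem sizes and numerical choices

The test suite and acceptance script run the reference configuration
(500 sites, ~33,000 window tests across contexts) in seconds and sweep
20 (tests) / 10 (script) null datasets of ~2,000 windows each — sizes
chosen so a single-workstation run of the whole suite stays in the
minutes range while keeping each estimate's Monte-Carlo error well below
the tolerance it is checked against.  Null calibration bounds use
nominal FDR + 3 binomial standard errors.  With only ~17–22 hyper-DMRs
at the reference conditions, decile 1 holds 2–3 regions, so the
decile-1 heritable fraction is a coarse estimate; the overall fraction
(n ≈ 20) is the stable readout and both are reported.  Exact-test
p-values agree with enumeration to < 1e−8 relative; the log-space
recurrence keeps underflow at bay down to p ≈ 1e−300.

## Known limitations

* Pooled-count exact tests ignore replicate dispersion (see above); the
  NB hook exists for users who need replicate-aware inference.
* Hyper-only DMR calling; hypo-methylation analyses are out of scope.
* Merged-region recomputation assumes window disjointness across sites;
  with overlapping anchors closer than a window, shared base pairs could
  be double-counted (not reachable under the simulator's separation).
* The observed/expected null permutes gene labels only; it does not
  preserve gene length, expression strength or local gene density.
* Genome-scale inputs (full plant genomes, tens of thousands of sites)
  are untested for memory; the design targets desk-scale reanalysis.
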