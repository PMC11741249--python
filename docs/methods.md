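# Methods

This note documents the models, conventions and numerical choices behind
each stage of `tmatlas`, and what the synthetic-data generators do and do
not emulate.

## Synthetic data model

**Expression counts.** Gene × cell counts are negative binomial with a
single global dispersion θ (variance μ + μ²/θ, default θ = 2, a typical
droplet-data value).  Relative gene expression is heavy-tailed
(log-normal, σ = 1.5) and normalised so the expected library size equals
`library_size_mean` (default 5,000 counts); per-cell library sizes vary
log-normally (σ = 0.25, unit mean).  Each cell class carries a disjoint
block of identity genes whose mean is multiplied by `marker_fold` (default
8) in that class only — distinct limbal cell types are separated by their
own expression programmes, so all six classes (three TM subtypes plus
three non-TM classes) get a block, with the TM blocks being the planted
"markers" that recovery tests look for.  Planted signature genes are
floored at the median base expression: curated marker genes are
detectable by construction, not drawn from the low-expression tail.  A
shared block up-shifted in both TM1 and TM2 (default 10 genes) plants the
expected topology in which TM1 and TM2 are molecularly closer to each
other than to TM3.  A fixed fraction of genes (default 5%) is flagged
mitochondrial and rescaled to hold exactly that share of expression, so
per-cell mitochondrial fractions concentrate near the nominal value and
QC behaves predictably.  The paper trail for the real data reports no
empirical dispersion or library-size distribution, so these defaults are
module parameters chosen once as field-realistic, not claims about any
particular dataset.

**Multiome companion.** Peak × cell counts are Poisson around
depth × peak-popularity means.  Each motif owns one TF and a random set of
member peaks.  For each planted TF a latent per-cell activity
(standard normal plus a subtype shift, emulating subtype-biased regulatory
programmes) multiplies both the TF's expression mean and — positively for
activators, negatively for repressors — the accessibility of its member
peaks, through `exp(coupling × activity)`.  Unplanted TFs are independent
of their motifs, giving an exact null.

**Sections.** A TM section is a rectangle-with-jitter in a rectified local
frame: axis 1 anterior→posterior (AP), axis 2 inner→outer (IO), inner edge
at depth 0.  AP length and IO depth are uniform on 125–200 μm and
15–30 μm — the study's inclusion windows — and the outer edge carries ±6%
depth jitter except across the AP midpoint, where it is flat so the
gate's midpoint depth measurement is exact.  Stain blobs are 16-gon discs
whose centres are drawn by rejection sampling with acceptance probability
proportional to the per-zone bias weights, then clipped to the TM.

**Mitochondria and nuclei.** A mitochondrion outer membrane is a jittered
ellipse scaled to a log-normal area (median 0.35 μm²); cristae are
disjoint 16-gon discs placed on a jittered grid whose pitch is set so the
summed disc area hits the target cristae fraction exactly (WT mean 0.40,
SD 0.06, clipped to [0.02, 0.95]).  Mutant traces scale the outer area by
`area_fold` and shift the cristae fraction additively; a shift pushing the
mean outside [0, 1] is rejected.  Nuclei are ellipsoids (a = b = r,
c = e·r) with subtype-dependent elongation e (TM1 ≈ 1.2, TM2/TM3 ≈ 2.5–2.8,
mirroring the short JCT-like versus elongated endothelial-like nuclear
shapes); the generator uses Thomsen's surface-area approximation
(p = 1.6075, error < 1.1%), which the tests check against a numerical
surface integral.

**Determinism.** Every generator is a pure function of its configuration;
one global seed is split into per-generator substreams by CRC-32 hashing
of the generator name into a `SeedSequence` spawn key, so regenerating one
input leaves the others unchanged.  Planted truth is always emitted as
separate metadata, never embedded in the data.

**What the generators do not emulate:** batch effects and cross-site
integration, doublets, read-level noise, sequence content (GC) of peaks,
curved real-tissue sections, or EM imaging artefacts.  Passing recovery
tests therefore show the procedures are implemented correctly and have
the expected power under clean planted structure, not that they are robust
to those real-data complications.

## Processing conventions

**QC.** Cell gates (expressed genes ≥ 200; mitochondrial fraction < 20%
single-cell / < 5% single-nucleus; multiome RNA and ATAC totals inside
their windows) are applied before the gene gate (expressed in > 3 of the
retained cells), and the filter is idempotent.  Normalisation is
ln(1 + 10,000·count/library), so `expm1` row sums per cell invert to
10,000 exactly.

**Clustering.** Genes are standardised across cells with values capped at
±10 (limits single-cell outlier leverage), projected onto the top
principal components (full SVD, deterministic), connected in a kNN graph
with shared-nearest-neighbour Jaccard weights, and partitioned by seeded
Leiden optimisation of RB-configuration modularity at the stated
resolution.  Cluster ids are relabelled by size for stable output.  Any
resolution-parameterised modularity optimiser with the same determinism
and recovery behaviour would be interchangeable here.

**Markers.** Wilcoxon rank-sum uses the normal approximation with tie
correction (exact enumeration is reserved for test oracles — cell numbers
make it infeasible in production, and the approximation tracks the exact
p within 0.02 already at 6-vs-6).  logFC is the natural log of mean
expm1-scale expression ratios with ε = 1e-9, matching the convention under
which the 0.25 gate is interpreted.  BH adjustment is used wherever an
"adjusted p" is required without a named method.  The marker panel gate is
strict (> 10% of cells, logFC > 0.25) and is applied *before* truncation
to the top 500 by p; gate-then-truncate makes the panel insensitive to how
many sub-threshold genes a cluster happens to have.

**Module score.** Genes are cut into 24 equal-frequency bins of average
expression (quantile bins keep occupancy stable); each deduplicated set
gene draws 100 controls from its bin, with replacement only when the bin
is smaller than the draw.  The score is mean(set) − mean(pooled controls)
per cell, seeded.

**Enrichment.** ORA is the upper-tail hypergeometric probability including
the observed overlap, inside an explicit universe (for subtype contrasts,
genes expressed in TM cells), BH-adjusted, reported at p ≤ 0.01 with the
full table alongside.  GSEA uses the weighted KS running sum (hit steps ∝
|stat|^weight, default weight 1; misses uniform), sign reported as
direction; ties in the ranking break by gene name for determinism.  The
null permutes gene labels (the analysis is preranked on DEG statistics, so
a phenotype permutation is not available); p is computed among same-sign
permuted scores and NES divides ES by the same-sign permutation mean
magnitude.  Permutation count (1,000) and weight are conventions of this
implementation, not reproductions of a stated protocol.

**Ligand rules.** Precedence is exclusive → shared-high → shared-low →
unassigned, which makes the rules mutually exclusive and exhaustive.
Exclusive requires one subtype > 1 CP10K and ≥ 4× (inclusive — "4× more"
counts) *every* other subtype; shared-high assigns the above-threshold
subtypes within 4× of the highest one, which reduces to the max/min-ratio
rule whenever the above-threshold subtypes are mutually comparable;
shared-low assigns all subtypes with non-zero expression when none clears
1 CP10K.  Both thresholds are parameters.

**TF screen.** Deviations follow the chromVAR construction:
(observed − expected)/expected per motif and cell, z-scored against 50
background peak sets matched on mean accessibility via equal-frequency
bins.  Background matching uses accessibility only — synthetic peaks have
no sequence, so GC matching is an extension point.  "Deviation above 75% of
all TFs" is operationalised as the 75th percentile of per-TF deviation
variability (SD of z across cells), the natural per-TF summary of
deviation magnitude.  Neighborhoods for the expression–activity
correlation are uniform random cell subsets (default size
min(100, n/2)); the embedding-local neighborhoods a full ATAC toolchain
would use require an embedding that is out of scope here.  Pearson p uses
the t distribution with n_neighborhoods − 2 df; TFs with zero RNA
expression are removed and those above 0.5 CP10K flagged as prioritized
(both bounds strict, matching the stated wording).

**Zones.** All cuts are straight lines in the rectified frame
(rectification of curved sections is input preparation, out of scope).
Halves cut at half the AP length, or at half the IO depth measured at the
AP midpoint.  The eight-zone scheme cuts three equal-length AP sectors;
each sector's average depth is area/AP-length (the natural polygon
analogue of "average depth was measured"); central and posterior sectors
split into three equal-depth bands, the thinner anterior sector into two.
The outermost band is unbounded above so the bands always partition the
sector exactly.  Occupancy normalises within section (percent of that
section's marker area), which is what makes different markers comparable;
sections with zero marker area are excluded rather than zero-filled,
because a within-section percentage is undefined there.  Inclusion bounds
(125–200 μm AP, 15–30 μm IO) are inclusive.  Cross-marker aggregation
weights sections equally within marker, then markers equally within
subtype.

**Morphometry.** Polygon areas are shoelace values with a simplicity check;
overlapping cristae are rejected rather than union-merged (the tracing
protocol implies disjoint folds, and rejection keeps areas additive).
Density per 100 μm² is averaged as mean-of-ratios across cells, not a
pooled ratio.  Genotype comparisons use the pooled-variance two-sided
Student's t with the mitochondrion as the replication unit (the stated
design of ~160–180 traces from 3 eyes per genotype implies trace-level
replication); an eye-level analysis can be run by aggregating per cell id
prefix first.  Per-cell sampling keeps up to 3 randomly chosen traces,
seeded.

**Pipeline.** The run config is a single YAML file validated by a strict
schema (unknown keys rejected); a resolved copy with all defaults
materialised is written into every run directory, along with a manifest of
SHA-256 digests for all outputs.  Reruns with the same config and seed are
bit-identical.  Stage functions read their inputs from the run directory,
so CLI verbs can execute stages independently; a missing upstream output
raises an error naming the required stage.

## Problem sizes and calibration checks

The standard recovery conditions are 6 classes × 300 cells, 2,000 genes,
marker fold 8 (clustering, markers, dendrogram, module scores); 200 TFs ×
2,000 peaks × 600 cells with 5 planted activators at unit coupling
(TF screen, 10 independent seeds, plus one uncoupled null run); 100 random
sections for partition geometry and 50 biased sections at 4:1
anterior:posterior weights for the bias test; 160 mitochondria per
genotype with area fold 2 and cristae shift −0.15; 200 replicates of the
ARI permutation null at 99 permutations.  The demo pipeline configuration
uses smaller sizes (40–80 cells per class) since it exercises plumbing
rather than statistical power.

## Known limitations

* The doublet-removal step of a full droplet workflow (flagging
  biologically incompatible expression profiles) is not operationalised;
  inputs are assumed doublet-free, as the synthetic data are.
* No batch integration: multi-sample designs must be harmonised upstream.
* GSEA significance at small set counts is limited by the permutation
  floor 1/(n_perm + 1).
* The eight-zone scheme assumes the rectified frame; strongly curved or
  torn sections violate it and should fail the inclusion gate upstream.
* Sphericity uses supplied volume and surface area; it does not segment
  nuclei from images.
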