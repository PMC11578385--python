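# Methods

`isoniche` implements the downstream spatial statistics of a spatial
isoform transcriptomics (SiT) experiment on Visium-style data: one spatial
cDNA library split between short reads (gene-level UMI counts per spot) and
long reads (full-length isoform counts per spot), with spots clustered into
spatially contiguous *niches*. Everything upstream — barcode/UMI
assignment, isoform calling, clustering, deconvolution — is treated as
input; everything downstream of the count matrices and niche labels is
implemented here.

## Spatial substrate

Visium arrays stagger spots so that array coordinates `(row, col)` satisfy
`col ≡ row (mod 2)`; every interior spot has six equidistant neighbors
`{(r, c±2), (r−1, c±1), (r+1, c±1)}`. `build_neighbor_graph` uses this
array adjacency when the coordinates form a consistent staggered grid and
falls back to Euclidean 6-nearest-neighbors in pixel space otherwise, with
ties broken on `(distance rounded to 1e-9, spot id)` so results are
reproducible across platforms. Edge spots keep fewer than six neighbors
rather than borrowing distant ones.

Two per-spot neighborhood statistics are defined on this graph:

* **Contact frequency** — the number of *distinct* niche labels among a
  spot's neighbors that differ from its own niche (range 0 to
  min(6, K−1)). The alternative reading — count the *neighbors* whose
  niche differs — is available as `count="neighbors"`; the distinct-label
  reading is the default because it is the primary definition.
* **Enrichment score** — for two focal cell populations A and B (here
  CD8+ CXCL13+ exhausted T cells and C1QC+ tumor-associated macrophages),
  `score(s) = [A at s]·#{n ∈ N(s): B at n} + [B at s]·#{n ∈ N(s): A at n}`,
  an integer in 0–12. Spots with score > 0 are *enrichment spots*. The
  defining description in the source protocol is garbled; this two-term
  formula is the formalization used throughout, it is symmetric under
  swapping A and B, and it is pinned against a literal brute-force recount
  in the tests.

Presence of A and B per spot is called either from marker panels
(default: all panel markers with count > 0; an `any` mode exists because
Visium spots are multicellular mixtures, so requiring every marker in one
spot is conservative) or from externally deconvolved cell-type fractions
thresholded at ≥ 0.6 (inclusive; the convention only states "cutoff 0.6").

## QC and normalization

Spots are removed when they detect fewer than 1000 genes (count > 0) or
exceed 5% mitochondrial UMI fraction; both bounds are strict, matching the
"<1000" / ">5%" phrasing, and "gene count" is the number of detected genes,
not the UMI total. Mitochondrial genes are identified by a configurable
name prefix (default `MT-`). Normalization is the standard library-size
log transform `ln(1 + 10⁴·count/total)`; it preserves the sparsity pattern
exactly and is a dialect choice, not a derived result.

## Isoform classes

Each isoform is classified relative to its gene and the niche map:
`single` (the gene's only isoform), `multi_all` (detected in every niche),
`multi_one` (exactly one niche), `multi_others` (≥ 2 niches but not all).
"Detected in a niche" means count > 0 in at least `detection_min_spots`
spots of that niche (default 1). This threshold is a free choice that
shifts the class proportions, so it is an explicit parameter rather than a
constant. Isoforms detected nowhere go to an `undetected` bucket excluded
from the four-way tally; this includes sole isoforms of a gene, so that
the four classes exactly partition the *detected* isoforms.

Expression patterns contrast three samples — tumor before chemotherapy
(Before), tumor after (After), metastatic lymph node (AfterLN) — via mean
normalized expression ratios: `metastasis_positive/negative` from
AfterLN vs After, `resistance/treatment_target` from After vs Before, at a
fold-change threshold of 1.5 (the classes are defined only verbally in the
source; the threshold and the use of means are this package's choices).
An isoform can satisfy both contrasts; all qualifying labels are kept and
the headline label is the one with the larger |log fold change|.

## Differential splicing screen

The screen mirrors the Seurat `FindMarkers` recipe: for every niche with
at least 3 spots on both sides, every isoform of a ≥ 2-isoform gene is
tested niche-vs-rest with a Wilcoxon rank-sum on log-normalized values;
`logFC = ln(mean(expm1 v_in)+1) − ln(mean(expm1 v_out)+1)` (the
Seurat dialect); `pct_in`/`pct_out` are detection fractions; Bonferroni is
applied over all tests performed in the run. A hit must be a
*nonmajority* isoform — not the gene's top bulk-count isoform (ties broken
lexicographically) — with adjusted p ≤ 0.05, |logFC| ≥ 0.25 and
max(pct) ≥ 0.1. The function takes raw counts and normalizes internally,
because the majority flag is defined on raw bulk counts.

The Wilcoxon test uses midranks for ties; when the pooled sample size is
≤ 12 the null distribution of the rank sum is enumerated exactly
(conditionally on the observed tie pattern), otherwise a normal
approximation with tie-corrected variance and continuity correction is
used. Student (pooled, default) and Welch t-tests and the Pearson
chi-square (no Yates correction by default; zero-margin rows/columns
dropped with a warning) are likewise implemented directly, with scipy
supplying only distribution tails; tests cross-check all three against
scipy's independent implementations to 1e-8 relative.

Degenerate inputs: identical constant samples give p = 1; zero pooled
variance with unequal means reports an infinite t and a p-value at the
smallest representable positive float.

## Ratio groups and association

The two-isoform ratio (motivating case CD74-202/CD74-201) is computed on
raw counts — within a spot the library size cancels, so raw and
normalized ratios coincide. Groups: High (ratio > 15), Medium
(1 < ratio ≤ 15), Low (ratio ≤ 1, denominator > 0), Others (denominator
0, ratio undefined). The printed definition of "Others" ("no CD74-201 or
no CD74-202 and CD74-201") is self-contradictory as written; the reading
adopted — Others ⇔ denominator = 0 — keeps Low well-defined at ratio 0
and makes the four groups a partition.

`association_report` relates grouping to enrichment three ways: the
Low/Medium/High × enrichment-spot 3×2 chi-square (Others excluded,
matching the three-group figure design) plus all 2×2 sub-tables, pairwise
t-tests of the enrichment score across groups, and a t-test of the ratio
in enrichment spots vs other spots (defined ratios only).

## Synthetic data

The generator plants ground truth for every downstream stage. Defaults
are fixed study conditions, not tuning knobs:

* **Lattice** 60×120 staggered grid → 3600 spots, unit pitch
  (`px_x = c/2`, `px_y = r·√3/2`, neighbor distance exactly 1).
* **Niches** K = 6 Voronoi cells of uniformly drawn seed spots (ties to
  the lower niche index); Voronoi cells of lattice points are connected,
  giving spatially contiguous niches.
* **Counts** negative binomial — the standard overdispersed model for
  spot counts — with mean 5 and dispersion 2 in supported niches and
  structural zeros elsewhere. Support encodes the planted class:
  `multi_all` all niches, `multi_one` one, `multi_others` a strict subset
  of ≥ 2; single-isoform genes get an arbitrary nonempty support. Genes
  draw 1–5 isoforms with P(1) = 0.5, which places ≈ 25% of isoforms in
  the `single` class and yields ≈ 1000 isoforms from 500 genes (≈ 2
  isoforms/gene). The mean of 5 makes detection certain in practice
  (P(a ≥ 20-spot niche is all zero) < 1e-20), so planted classes are
  exactly recoverable — by construction, this validates the classifier's
  logic, not its behavior on noisy detection boundaries.
* **Gene matrix** = per-spot sum of each gene's isoform counts
  (conservation holds exactly), plus marker genes and the ratio gene.
* **Colocalization** — a contiguous zone (BFS growth on the hex graph
  from a random seed spot) covering 20% of spots. Inside it, joint
  presence of the two focal types has its odds multiplied by
  `coloc_odds` (default 8; marginal presence 0.3 each), and the
  designated isoform pair is drawn with denominator 1 + Poisson(0.2) and
  numerator Poisson(25·denominator), putting the ratio above 15 with
  probability ≈ 0.98. Outside, presence is independent and the pair is
  Poisson(0.5)/Poisson(2.0), concentrating the ratio at ≤ 1 with ≈ 14%
  undefined (Others). Marker genes are positive exactly where their type
  is planted present. The planted TAM panel omits CD74 (which the real
  panel includes) because CD74 doubles as the ratio gene and is expressed
  broadly; keeping it would contradict "markers > 0 exactly where
  planted".
* **Expression patterns** — per-isoform pattern drawn from
  {none 0.6, each pattern 0.1}; Before/AfterLN matrices re-draw counts
  with the niche means scaled by 3 (or 1/3) according to the pattern.
* **Determinism** — one integer seed feeds independent child generators
  (SeedSequence spawning); the same config reproduces a byte-identical
  on-disk bundle.

What the generator does *not* emulate: realistic transcriptome-wide
correlation structure, segmentation/image noise, spot-level cell-count
variation, or ambient RNA. Passing tests therefore demonstrate
correctness of the statistics on data satisfying the model's assumptions,
not robustness to those artifacts.

## Pipeline

`run_pipeline` executes QC → normalize → neighbor graph → contact
frequency → isoform classes → (expression patterns when a Before/AfterLN
trio is present) → differential splicing → presence → enrichment → ratio
groups → association report, writing TSV/JSON outputs and a manifest with
the resolved config, input checksums, per-stage row counts and timings.
The default synthetic run (3600 spots, 500 genes, ≈ 1000 isoforms, ≈ 4800
differential tests) completes in well under a minute on one CPU and
reruns byte-identically under a fixed seed. For real inputs, niche labels
must be supplied (`truth_spots.tsv` layout); clustering is out of scope.

## Known limitations

* **Spot-level contingency tests on spatial data are anti-conservative.**
  The association chi-square treats spots as independent draws. With the
  planted design — the High group is one contiguous zone, and the
  enrichment indicator is autocorrelated because neighboring spots share
  neighborhoods — the cell-count variance exceeds the multinomial
  variance, and the null rejection rate at α = 0.05 is ≈ 0.09 rather than
  0.05 (measured over 1000 null simulations; the identical chi-square
  implementation is exactly calibrated on iid multinomial draws, and the
  zone-vs-joint-presence test, whose sampling *is* iid per spot, is
  nominal). This caveat applies equally to any spot-level chi-square on
  spatially structured Visium data; p-values near the threshold should be
  interpreted with care, e.g. against a rotation/permutation null. The
  acceptance suite keeps one red test documenting this behavior.
* The niche-similarity metric reported in the motivating study
  (58.7–76.3%) is not defined there; `niche_agreement` emits both
  Hungarian-matched label overlap and ARI without asserting either is the
  original metric.
* `classify_pattern` uses unpaired per-sample means; it does not model
  per-spot pairing or compositional effects of normalization across
  samples.
* Exact Wilcoxon enumeration is limited to pooled n ≤ 12 (924
  combinations at 6+6); beyond that the tie-corrected normal
  approximation is used, which the tests show is within 0.02 of exact at
  8+8.
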