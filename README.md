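# isoniche

Niche-aware spatial statistics for isoform-resolved Visium data.

Spatial isoform transcriptomics (SiT) splits one spatially barcoded cDNA
library between short-read sequencing (gene-level UMI counts per spot) and
long-read sequencing (full-length transcript isoforms per spot). With
spots clustered into spatially contiguous *niches*, a set of bespoke
downstream statistics becomes possible — and `isoniche` implements them as
a tested, reusable library for anyone analyzing such data:

* **Hexagonal neighborhood structure** — the Visium six-neighbor graph,
  per-spot **contact frequency** (number of distinct foreign niches among
  a spot's six neighbors), niche-label agreement between clusterings
  (Hungarian-matched overlap and ARI), and per-spot-pair transcriptome
  correlation between assays.
* **Spatial isoform classes** — each isoform labeled `single` (its gene's
  only isoform), `multi_all` (detected in every niche), `multi_one`
  (exactly one niche) or `multi_others` (≥ 2 but not all), plus
  cross-sample expression patterns (metastasis positive/negative,
  resistance, treatment target).
* **Differential splicing screen** — Wilcoxon rank-sum niche-vs-rest per
  isoform of multi-isoform genes (logFC ≥ 0.25, min.pct 0.1, Bonferroni
  ≤ 0.05), keeping only *nonmajority* isoforms.
* **Colocalization enrichment** — per-spot presence of two focal cell
  populations (CD8⁺ CXCL13⁺ exhausted T cells and C1QC⁺ TAMs, from marker
  panels or deconvolved fractions) and the neighborhood **enrichment
  score** `score(s) = [A at s]·#{B neighbors} + [B at s]·#{A neighbors}`,
  an integer 0–12; spots with score > 0 are *enrichment spots*.
* **Isoform-ratio association** — per-spot two-isoform expression ratio
  (e.g. CD74-202/CD74-201) grouped as High (> 15), Medium (1, 15], Low
  (≤ 1) or Others (denominator 0), related to enrichment with
  first-principles chi-square and t-tests.
* **Synthetic data with planted truth** — a generator producing
  Visium-style bundles (MTX + positions CSV + TSVs) with known niches,
  isoform classes, expression patterns and a planted
  high-ratio/colocalization zone, so every statistic can be validated
  against ground truth and its power and calibration measured.

All file formats are the Space Ranger dialects (tissue positions CSV,
MTX + features/barcodes TSV). The statistical tests are implemented from
first principles and cross-checked against independent references in the
test suite. See `docs/methods.md` for models, assumptions, defaults and
known limitations.

## Worked example

Run the full pipeline on the default synthetic dataset (3600 spots, 500
genes, ≈ 1000 isoforms, 6 niches, a planted colocalization zone covering
20% of spots with joint-presence odds ×8):

```python
from isoniche import default_synthetic_config, run_pipeline

cfg = default_synthetic_config(output_dir="demo_out", seed=0)
manifest = run_pipeline(cfg)
```

or, from a shell, `isoniche run --seed 0 --out demo_out`. Key numbers
from `demo_out/` at seed 0:

* `class_distribution.json` — single 27.0%, multi_all 24.2%, multi_one
  5.5%, multi_others 43.3% of detected isoforms: the four classes
  partition the detected isoforms, and the `single` share tracks the
  planted fraction of single-isoform genes.
* `association_report.json` — ratio-group sizes Low 2373 / Medium 101 /
  High 708 / Others 418; the Low/Medium/High × enrichment-spot chi-square
  gives statistic 171.2 (df 2, p ≈ 7e-38), and the ratio in enrichment
  spots exceeds other spots with t = 13.2 (p ≈ 2e-38): the planted
  association between a high isoform ratio and colocalization of the two
  cell populations is recovered decisively.
* `enrichment_summary.json` — 71.0% of High-ratio spots are enrichment
  spots vs 43.1% of Low-ratio spots: the planted effect concentrates
  enrichment where the ratio is high.

Narrative scripts in `examples/` walk through each capability separately
(lattice and contact frequency, isoform classes, differential splicing,
enrichment scoring, ratio association).

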