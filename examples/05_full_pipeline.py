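"""End-to-end run: generate a synthetic bundle, push it through every
stage, and read the headline numbers from the outputs.

Equivalent shell command: `isoniche run --seed 0 --out demo_out`.
"""

import json
import warnings
from pathlib import Path

from isoniche import default_synthetic_config, run_pipeline

outdir = Path("demo_out")
cfg = default_synthetic_config(output_dir=str(outdir), seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_pipeline(cfg)

print(f"stages run: {', '.join(manifest['stages'])}")
print(f"total wall clock: {manifest['total_seconds']} s")

classes = json.loads((outdir / "class_distribution.json").read_text())
print("isoform classes (% of detected):",
      {k: round(v, 1) for k, v in classes["percent"].items()})

report = json.loads((outdir / "association_report.json").read_text())
chi = report["chi_square"]
print(f"ratio-group x enrichment chi-square: {chi['statistic']:.1f} "
      f"(df {int(chi['df'])}, p = {chi['pvalue']:.2e})")
print("group sizes:", report["group_sizes"])

summary = json.loads((outdir / "enrichment_summary.json").read_text())
for grp in ("Low", "Medium", "High"):
    d = summary["by_group"][grp]
    if d["n_spots"]:
        print(f"  {grp:6s}: {100 * d['n_enrichment_spots'] / d['n_spots']:.1f}% "
              f"of {d['n_spots']} spots are enrichment spots")
print("-> the planted high-ratio zone concentrates colocalization of the "
      "two focal cell populations; rerunning with the same seed "
      "reproduces these files byte-identically.")
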