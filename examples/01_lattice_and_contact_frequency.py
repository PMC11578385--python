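"""Build a Visium-style hexagonal lattice, plant niches, and measure how
often each spot touches foreign niches.

The contact frequency of a spot is the number of distinct niche labels,
different from its own, among its six nearest neighbors — a per-spot
measure of how interleaved the tissue domains are.
"""

import numpy as np

from isoniche import (build_hex_lattice, build_neighbor_graph,
                      compare_contact_frequency, contact_frequency,
                      plant_niches)

lattice = build_hex_lattice(n_rows=30, n_cols=60)
graph = build_neighbor_graph(lattice)
print(f"lattice: {lattice.n_spots} spots; "
      f"interior degree = {graph.degree().max()} (hexagonal)")

# Two niche maps: coarse (4 domains) vs fragmented (12 domains).
coarse = plant_niches(lattice, 4, seed=1)
fragmented = plant_niches(lattice, 12, seed=1)

cf_coarse = contact_frequency(graph, coarse)
cf_frag = contact_frequency(graph, fragmented)
print(f"mean contact frequency: coarse K=4 -> {cf_coarse.mean():.3f}, "
      f"fragmented K=12 -> {cf_frag.mean():.3f}")

res = compare_contact_frequency({"coarse": cf_coarse, "fragmented": cf_frag})
row = res.iloc[0]
print(f"unpaired t-test coarse vs fragmented: t = {row.t:.2f}, "
      f"p = {row.pvalue:.2e}")
print("-> more, smaller niches mean more boundary spots, so contact "
      "frequency rises; the t-test quantifies that shift.")
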