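"""Hexagonal neighborhood structure and niche-level spatial statistics.

Visium arrays stagger spots so that each interior spot has six equidistant
neighbors.  In array coordinates (where column parity alternates by row) the
six neighbors of ``(r, c)`` are ``(r, c±2)``, ``(r−1, c±1)`` and
``(r+1, c±1)``.  For lattices that only carry pixel coordinates the six
nearest spots by Euclidean distance are used instead, with ties broken on
``(distance, spot_id)`` for reproducibility.

The per-spot *contact frequency* is the number of distinct niche labels,
different from the spot's own, found among its six neighbors.  An
alternative reading — the number of neighboring *spots* whose niche differs
— is available via ``count="neighbors"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from ._errors import IntegrityError
from .io import SpotLattice
from .stats import t_test_unpaired

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "contact_frequency",
    "compare_contact_frequency",
    "niche_agreement",
    "spot_pair_correlation",
]

_HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class NeighborGraph:
    """Per-spot ordered neighbor lists (at most six each)."""

    spot_ids: list
    neighbors: dict  # spot_id -> list of neighbor spot_ids

    def degree(self) -> pd.Series:
        return pd.Series({s: len(self.neighbors[s]) for s in self.spot_ids})

    def is_symmetric(self) -> bool:
        nb = {s: set(v) for s, v in self.neighbors.items()}
        return all(s in nb[t] for s, ts in nb.items() for t in ts)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(s, t) for s in self.spot_ids for t in self.neighbors[s]]
        return pd.DataFrame(rows, columns=["spot_id", "neighbor_id"])


def build_neighbor_graph(lattice: SpotLattice, k: int = 6) -> NeighborGraph:
    """Six-nearest-neighbor graph of a spot lattice.

    Array adjacency is used when the lattice has consistent staggered
    coordinates; otherwise falls back to Euclidean k-NN in pixel space.
    Edge spots keep fewer than ``k`` neighbors in array mode.
    """
    n = lattice.n_spots
    if n < 2:
        import warnings

        warnings.warn("fewer than 2 spots: empty neighbor graph", stacklevel=2)
        return NeighborGraph(list(lattice.spot_id), {s: [] for s in lattice.spot_id})
    if not lattice.pixel_only and k == 6:
        index = {
            (r, c): s
            for r, c, s in zip(lattice.array_row, lattice.array_col, lattice.spot_id)
        }
        neighbors = {}
        for r, c, s in zip(lattice.array_row, lattice.array_col, lattice.spot_id):
            neighbors[s] = [
                index[(r + dr, c + dc)]
                for dr, dc in _HEX_OFFSETS
                if (r + dr, c + dc) in index
            ]
        return NeighborGraph(list(lattice.spot_id), neighbors)

    # Euclidean fallback: k nearest by (distance, spot_id).
    xy = np.column_stack([lattice.px_x, lattice.px_y])
    tree = cKDTree(xy)
    kq = min(n, k + 1)
    dist, idx = tree.query(xy, k=kq)
    neighbors = {}
    ids = lattice.spot_id
    for i, s in enumerate(ids):
        cand = [(round(float(d), 9), str(ids[j]), j)
                for d, j in zip(dist[i], idx[i]) if j != i]
        cand.sort()
        neighbors[s] = [ids[j] for _, _, j in cand[:k]]
    return NeighborGraph(list(ids), neighbors)


def contact_frequency(graph: NeighborGraph, niches: Mapping, count: str = "niches") -> pd.Series:
    """Per-spot contact with foreign niches.

    count="niches"    -> number of DISTINCT niche labels among the neighbors
                         that differ from the spot's own niche (default).
    count="neighbors" -> number of neighboring spots whose niche differs.
    """
    if count not in ("niches", "neighbors"):
        raise ValueError("count must be 'niches' or 'neighbors'")
    out = {}
    for s in graph.spot_ids:
        if s not in niches:
            raise IntegrityError(f"spot {s!r} has no niche label")
        own = niches[s]
        foreign = []
        for t in graph.neighbors[s]:
            if t not in niches:
                raise IntegrityError(f"neighbor {t!r} of {s!r} has no niche label")
            if niches[t] != own:
                foreign.append(niches[t])
        out[s] = len(set(foreign)) if count == "niches" else len(foreign)
    return pd.Series(out, name="contact_frequency", dtype=int)


def compare_contact_frequency(samples: Mapping[str, Sequence]) -> pd.DataFrame:
    """Pairwise unpaired two-tailed t-tests of contact frequency across samples.

    ``samples`` maps sample name -> per-spot contact-frequency vector.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two samples to compare")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x = np.asarray(samples[a], dtype=float)
            y = np.asarray(samples[b], dtype=float)
            res = t_test_unpaired(x, y, variant="student")
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "mean_a": x.mean(),
                    "mean_b": y.mean(),
                    "mean_diff": x.mean() - y.mean(),
                    "t": res.statistic,
                    "df": res.df,
                    "pvalue": res.pvalue,
                }
            )
    return pd.DataFrame(rows)


def niche_agreement(labels_a: Mapping, labels_b: Mapping, method: str = "matched") -> float:
    """Agreement between two niche labelings of the same spots.

    method="matched" -> best achievable fraction of spots with identical
    labels over all one-to-one label correspondences (Hungarian assignment on
    the confusion matrix).  Invariant to renaming labels in either input.
    method="ari" -> adjusted Rand index, an alternative chance-corrected
    agreement measure.
    """
    spots = sorted(labels_a)
    if sorted(labels_b) != spots:
        raise IntegrityError("labelings cover different spot sets")
    if not spots:
        raise IntegrityError("empty labelings")
    a = pd.Series([labels_a[s] for s in spots])
    b = pd.Series([labels_b[s] for s in spots])
    if method == "ari":
        from sklearn.metrics import adjusted_rand_score

        return float(adjusted_rand_score(a, b))
    if method != "matched":
        raise ValueError("method must be 'matched' or 'ari'")
    conf = pd.crosstab(a, b).to_numpy()
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return float(conf[rows, cols].sum() / len(spots))


def spot_pair_correlation(mat_a, mat_b, pairing: Mapping | None = None) -> pd.Series:
    """Per-spot-pair Pearson correlation between two assays.

    Both matrices must share a feature space.  ``pairing`` maps spot ids of
    A to spot ids of B; by default identical barcodes are paired.  Pairs
    where either profile has zero variance get NaN.
    """
    if mat_a.features != mat_b.features:
        raise IntegrityError("matrices must share an identical feature space")
    if pairing is None:
        common = [s for s in mat_a.spots if s in set(mat_b.spots)]
        pairing = {s: s for s in common}
    if not pairing:
        raise IntegrityError("no spot pairs to correlate")
    A = mat_a.subset_spots(list(pairing)).counts.toarray().astype(float)
    B = mat_b.subset_spots([pairing[s] for s in pairing]).counts.toarray().astype(float)
    A -= A.mean(axis=1, keepdims=True)
    B -= B.mean(axis=1, keepdims=True)
    denom = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (A * B).sum(axis=1) / denom, np.nan)
    return pd.Series(r, index=list(pairing), name="pearson_r")
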