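"""Per-spot presence calls for two focal cell populations and the
hexagonal-neighborhood enrichment score.

Presence can be called two ways: from marker panels on the gene matrix
(a cell type is present where its markers have positive counts — by
default ALL markers, with an ``any`` mode since Visium spots are
multicellular mixtures), or from externally deconvolved cell-type
fractions thresholded at a cutoff (default 0.6, inclusive).

The enrichment score of a spot s with neighbor set N(s) (its six nearest
spots) is

    score(s) = [A at s] * #{n in N(s): B at n} + [B at s] * #{n in N(s): A at n}

i.e. the number of neighbors carrying the complementary type, summed over
both directions when the focal spot carries both types.  Spots with
score > 0 are "enrichment spots".  A looser region flag marks spots whose
closed neighborhood {s} ∪ N(s) contains both types at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, IntegrityError
from .hexgrid import NeighborGraph

__all__ = [
    "MarkerPanel",
    "TEX_PANEL",
    "TAM_PANEL",
    "call_presence_markers",
    "call_presence_fractions",
    "enrichment_score",
    "enrichment_summary",
]


@dataclass(frozen=True)
class MarkerPanel:
    """A named cell type with its marker genes and combination rule."""

    type_name: str
    markers: tuple
    rule: str = "all"

    def __post_init__(self) -> None:
        if not self.markers:
            raise ConfigError("marker panel needs at least one gene")
        if self.rule not in ("all", "any"):
            raise ConfigError("rule must be 'all' or 'any'")


# The focal populations: exhausted CD8+ CXCL13+ T cells and C1QC+ TAMs.
TEX_PANEL = MarkerPanel("CD8_CXCL13_Tex", ("CD8A", "CXCL13", "CD3E", "PDCD1"))
TAM_PANEL = MarkerPanel("C1QC_TAM", ("C1QC", "LYZ", "CD74", "APOE", "CSF1R"))


def _panel_presence(gene_matrix, panel: MarkerPanel) -> np.ndarray:
    missing = [g for g in panel.markers if g not in gene_matrix.features]
    if missing:
        raise ConfigError(f"panel {panel.type_name!r}: markers absent from matrix: {missing}")
    cols = np.column_stack([gene_matrix.column(g) > 0 for g in panel.markers])
    return cols.all(axis=1) if panel.rule == "all" else cols.any(axis=1)


def call_presence_markers(gene_matrix, panel_a: MarkerPanel, panel_b: MarkerPanel) -> pd.DataFrame:
    """Presence of both focal types from marker expression (> 0) per spot."""
    return pd.DataFrame(
        {
            "present_a": _panel_presence(gene_matrix, panel_a),
            "present_b": _panel_presence(gene_matrix, panel_b),
            "provenance": "marker",
        },
        index=pd.Index(gene_matrix.spots, name="spot_id"),
    )


def call_presence_fractions(fractions: pd.DataFrame, type_a: str, type_b: str,
                            cutoff: float = 0.6) -> pd.DataFrame:
    """Presence from deconvolved per-spot cell-type fractions (>= cutoff)."""
    for col in (type_a, type_b):
        if col not in fractions.columns:
            raise ConfigError(f"cell type {col!r} absent from fraction table")
        vals = fractions[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise IntegrityError(f"fractions for {col!r} outside [0, 1]")
    return pd.DataFrame(
        {
            "present_a": fractions[type_a].to_numpy(dtype=float) >= cutoff,
            "present_b": fractions[type_b].to_numpy(dtype=float) >= cutoff,
            "provenance": "fraction",
        },
        index=fractions.index.rename("spot_id"),
    )


def enrichment_score(graph: NeighborGraph, presence: pd.DataFrame) -> pd.DataFrame:
    """Neighborhood enrichment score per spot (0-12) and derived flags."""
    missing = [s for s in graph.spot_ids if s not in presence.index]
    if missing:
        raise IntegrityError(f"spots without presence calls: {missing[:5]}")
    pa = presence["present_a"].to_dict()
    pb = presence["present_b"].to_dict()
    rows = []
    for s in graph.spot_ids:
        nb = graph.neighbors[s]
        unknown = [t for t in nb if t not in pa]
        if unknown:
            raise IntegrityError(f"neighbors without presence calls: {unknown[:5]}")
        n_b = sum(bool(pb[t]) for t in nb)
        n_a = sum(bool(pa[t]) for t in nb)
        score = (int(bool(pa[s])) * n_b) + (int(bool(pb[s])) * n_a)
        region = (bool(pa[s]) or n_a > 0) and (bool(pb[s]) or n_b > 0)
        rows.append((s, score, score > 0, region))
    return pd.DataFrame(
        rows, columns=["spot_id", "score", "is_enrichment_spot", "in_enriched_region"]
    ).set_index("spot_id")


def enrichment_summary(result: pd.DataFrame, groups: pd.Series | None = None) -> dict:
    """Summarize enrichment calls, optionally per spot group.

    Per group: spot count, enrichment-spot count and fraction (None for an
    empty group rather than 0 — absence of evidence is not a zero rate).
    """
    out = {
        "n_spots": int(len(result)),
        "n_enrichment_spots": int(result["is_enrichment_spot"].sum()),
        "score_distribution": {
            int(k): int(v) for k, v in result["score"].value_counts().sort_index().items()
        },
    }
    if groups is not None:
        per_group = {}
        levels = (groups.cat.categories if isinstance(groups.dtype, pd.CategoricalDtype)
                  else sorted(groups.dropna().unique(), key=str))
        for lvl in levels:
            members = result.loc[groups.index[groups == lvl].intersection(result.index)]
            n = int(len(members))
            n_enriched = int(members["is_enrichment_spot"].sum())
            per_group[str(lvl)] = {
                "n_spots": n,
                "n_enrichment_spots": n_enriched,
                "fraction_enriched": (n_enriched / n) if n else None,
            }
        out["by_group"] = per_group
    return out
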