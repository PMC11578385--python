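"""Synthetic Visium-style datasets with planted ground truth.

The generator emulates the statistical structure the downstream stages
assume: a staggered hexagonal lattice of spots, K spatially contiguous
niches (Voronoi cells of random seed spots), negative-binomial gene and
isoform counts whose niche support encodes the planted spatial class of
each isoform, two focal cell populations whose joint presence odds are
multiplied inside a contiguous high-ratio zone, and a designated isoform
pair whose expression ratio exceeds the High threshold inside that zone.

Every quantity is drawn from a single integer seed through independent
child generators, so a given ``SimConfig`` reproduces its dataset exactly
— including byte-identical on-disk bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._errors import ConfigError
from .io import CountMatrix, SpotLattice, write_counts, write_positions

__all__ = [
    "SimConfig",
    "GroundTruth",
    "build_hex_lattice",
    "plant_niches",
    "simulate_counts",
    "plant_colocalization",
    "simulate_sample_trio",
    "generate_dataset",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Lattice: ``n_rows`` x ``n_cols`` staggered grid (half the columns are
    valid per row, so the default 60 x 120 yields 3600 spots) carved into
    ``n_niches`` Voronoi niches.

    Counts: genes draw their isoform count from ``isoforms_per_gene``
    (default: half the genes are single-isoform, which places ~25% of
    isoforms in the "single" class); each isoform of a multi-isoform gene
    draws its spatial class from the renormalized multi entries of
    ``class_mix`` and is expressed NB(``nb_mean``, ``nb_dispersion``) in
    its supported niches and structurally zero elsewhere.

    Colocalization: a contiguous zone covering ``ratio_zone_fraction`` of
    the lattice multiplies the joint-presence odds of the two focal cell
    types by ``coloc_odds`` (marginal presence probability
    ``base_presence`` each); inside the zone the designated isoform pair is
    drawn with numerator mean ``zone_ratio_mean`` per denominator copy so
    the ratio lands above the High threshold with probability ~0.98.
    """

    seed: int = 0
    n_rows: int = 60
    n_cols: int = 120
    n_niches: int = 6
    n_genes: int = 500
    isoforms_per_gene: dict = field(
        default_factory=lambda: {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    nb_mean: float = 5.0
    nb_dispersion: float = 2.0
    class_mix: dict = field(
        default_factory=lambda: {
            "single": 0.25, "multi_all": 0.25, "multi_one": 0.05, "multi_others": 0.45
        }
    )
    coloc_odds: float = 8.0
    base_presence: float = 0.3
    ratio_zone_fraction: float = 0.2
    zone_ratio_mean: float = 25.0
    zone_denom_extra_mean: float = 0.2
    out_zone_num_mean: float = 0.5
    out_zone_denom_mean: float = 2.0
    tex_markers: tuple = ("CD8A", "CXCL13", "CD3E", "PDCD1")
    tam_markers: tuple = ("C1QC", "LYZ", "APOE", "CSF1R")
    ratio_gene: str = "CD74"
    ratio_pair: tuple = ("CD74-202", "CD74-201")
    pattern_mix: dict = field(
        default_factory=lambda: {
            "none": 0.6, "metastasis_positive": 0.1, "metastasis_negative": 0.1,
            "resistance": 0.1, "treatment_target": 0.1,
        }
    )
    pattern_fc: float = 3.0
    emit_trio: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("lattice dimensions must be >= 1")
        if self.n_niches < 1:
            raise ConfigError("n_niches must be >= 1")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix must sum to 1")
        if abs(sum(self.isoforms_per_gene.values()) - 1.0) > 1e-9:
            raise ConfigError("isoforms_per_gene must sum to 1")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("negative-binomial parameters must be positive")
        if self.coloc_odds < 1:
            raise ConfigError("coloc_odds must be >= 1")
        if not (0 < self.base_presence < 1):
            raise ConfigError("base_presence must be in (0, 1)")
        if not (0 < self.ratio_zone_fraction < 1):
            raise ConfigError("ratio_zone_fraction must be in (0, 1)")
        if self.class_mix.get("multi_one", 0) > 0 and self.n_niches < 2:
            raise ConfigError("multi_one isoforms need at least 2 niches")
        if self.class_mix.get("multi_others", 0) > 0 and self.n_niches < 3:
            raise ConfigError("multi_others isoforms need at least 3 niches")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tex_markers"] = list(self.tex_markers)
        d["tam_markers"] = list(self.tam_markers)
        d["ratio_pair"] = list(self.ratio_pair)
        d["isoforms_per_gene"] = {str(k): v for k, v in self.isoforms_per_gene.items()}
        return d


@dataclass
class GroundTruth:
    """Planted truth for one generated dataset."""

    niches: dict                       # spot_id -> niche label
    spatial_class: pd.Series           # isoform -> class
    support: dict                      # isoform -> tuple of supported niches
    pattern: pd.Series                 # isoform -> expression pattern
    presence: pd.DataFrame             # spot x (present_a, present_b)
    zone: pd.Series                    # spot -> bool, high-ratio zone
    config: SimConfig


def build_hex_lattice(n_rows: int, n_cols: int) -> SpotLattice:
    """Staggered hexagonal lattice: spots at (r, c) with c ≡ r (mod 2).

    Pixel coordinates use unit pitch: px_x = c/2, px_y = r·√3/2, so every
    pair of array-adjacent spots is at Euclidean distance exactly 1.
    """
    if n_rows < 1 or n_cols < 1:
        raise ConfigError("lattice dimensions must be >= 1")
    rows, cols = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            if c % 2 == r % 2:
                rows.append(r)
                cols.append(c)
    rows = np.array(rows)
    cols = np.array(cols)
    ids = np.array([f"spot_{r:03d}_{c:03d}" for r, c in zip(rows, cols)], dtype=object)
    return SpotLattice(
        spot_id=ids,
        in_tissue=np.ones(len(ids), dtype=bool),
        array_row=rows,
        array_col=cols,
        px_x=cols / 2.0,
        px_y=rows * (np.sqrt(3.0) / 2.0),
    )


def plant_niches(lattice: SpotLattice, k: int, seed: int) -> dict:
    """Voronoi niches: K uniformly drawn seed spots; each spot takes the
    label of its nearest seed in pixel distance, ties to the lower index."""
    n = lattice.n_spots
    if k > n:
        raise ConfigError(f"cannot plant {k} niches on {n} spots")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n, size=k, replace=False)
    xy = np.column_stack([lattice.px_x, lattice.px_y])
    d = np.linalg.norm(xy[:, None, :] - xy[seeds][None, :, :], axis=2)
    labels = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    return {s: int(lab) for s, lab in zip(lattice.spot_id, labels)}


def _nb_draw(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _plan_isoforms(cfg: SimConfig, rng) -> pd.DataFrame:
    """Gene architecture + per-isoform class and niche support."""
    k_vals = np.array(sorted(cfg.isoforms_per_gene), dtype=int)
    k_probs = np.array([cfg.isoforms_per_gene[k] for k in k_vals], dtype=float)
    n_iso_per_gene = rng.choice(k_vals, size=cfg.n_genes, p=k_probs / k_probs.sum())

    multi_classes = ["multi_all", "multi_one", "multi_others"]
    w = np.array([cfg.class_mix.get(c, 0.0) for c in multi_classes], dtype=float)
    if w.sum() <= 0:
        w = np.array([1.0, 0.0, 0.0])
    w = w / w.sum()
    K = cfg.n_niches
    all_niches = np.arange(K)

    rows = []
    for gi in range(cfg.n_genes):
        gene = f"G{gi:04d}"
        n_iso = int(n_iso_per_gene[gi])
        for t in range(n_iso):
            iso = f"{gene}-2{t + 1:02d}"
            if n_iso == 1:
                cls = "single"
                size = int(rng.integers(1, K + 1))
                support = tuple(sorted(rng.choice(all_niches, size=size, replace=False).tolist()))
            else:
                cls = multi_classes[int(rng.choice(3, p=w))]
                if cls == "multi_all":
                    support = tuple(range(K))
                elif cls == "multi_one":
                    support = (int(rng.integers(0, K)),)
                else:
                    size = int(rng.integers(2, K))  # strict subset, >= 2
                    support = tuple(sorted(rng.choice(all_niches, size=size, replace=False).tolist()))
            rows.append((iso, gene, cls, support))
    return pd.DataFrame(rows, columns=["isoform_id", "gene_id", "class", "support"])


def _draw_iso_counts(plan: pd.DataFrame, niche_idx: np.ndarray, cfg: SimConfig, rng,
                     mean_mult: pd.Series | None = None) -> sp.csr_matrix:
    """Spots x isoforms counts: NB(nb_mean * mult) in supported niches, 0 elsewhere."""
    n_spots = len(niche_idx)
    cols = []
    for iso, support in zip(plan["isoform_id"], plan["support"]):
        mult = 1.0 if mean_mult is None else float(mean_mult[iso])
        col = np.zeros(n_spots, dtype=np.int64)
        mask = np.isin(niche_idx, list(support))
        col[mask] = _nb_draw(rng, cfg.nb_mean * mult, cfg.nb_dispersion, int(mask.sum()))
        cols.append(col)
    return sp.csr_matrix(np.column_stack(cols))


def simulate_counts(cfg: SimConfig, lattice: SpotLattice, niches: dict, rng=None):
    """Draw gene- and isoform-level count matrices with planted classes.

    Returns ``(gene_matrix, iso_matrix, plan)`` where ``plan`` carries the
    per-isoform planted class and niche support.  The gene-level count of a
    gene at a spot is exactly the sum of its isoforms' counts there.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    plan = _plan_isoforms(cfg, rng)
    niche_idx = np.array([niches[s] for s in lattice.spot_id])
    iso_counts = _draw_iso_counts(plan, niche_idx, cfg, rng)

    iso2gene = dict(zip(plan["isoform_id"], plan["gene_id"]))
    spots = [str(s) for s in lattice.spot_id]
    iso_matrix = CountMatrix(
        spots=spots, features=plan["isoform_id"].tolist(), counts=iso_counts,
        level="isoform", iso2gene=iso2gene,
    )
    genes = sorted(plan["gene_id"].unique())
    gene_pos = {g: i for i, g in enumerate(genes)}
    agg = sp.csr_matrix(
        (np.ones(len(plan)), (np.arange(len(plan)), [gene_pos[g] for g in plan["gene_id"]])),
        shape=(len(plan), len(genes)),
    )
    gene_matrix = CountMatrix(
        spots=spots, features=genes, counts=(iso_counts @ agg).astype(np.int64), level="gene"
    )
    return gene_matrix, iso_matrix, plan


@dataclass
class ColocTruth:
    """Planted colocalization structure."""

    presence: pd.DataFrame     # spot x (present_a, present_b)
    pair_counts: pd.DataFrame  # spot x (count_a, count_b)
    zone: pd.Series            # spot -> bool
    marker_counts: pd.DataFrame  # spot x marker genes


def _grow_zone(lattice: SpotLattice, fraction: float, rng) -> np.ndarray:
    """Contiguous zone of ~fraction of spots grown by BFS on the hex graph."""
    from .hexgrid import build_neighbor_graph

    n = lattice.n_spots
    target = max(1, int(round(fraction * n)))
    graph = build_neighbor_graph(lattice)
    pos = {s: i for i, s in enumerate(lattice.spot_id)}
    in_zone = np.zeros(n, dtype=bool)
    order = rng.permutation(n)
    oi = 0
    queue: list = []
    while in_zone.sum() < target:
        if not queue:
            while oi < n and in_zone[order[oi]]:
                oi += 1
            queue.append(int(order[oi]))
            in_zone[order[oi]] = True
        i = queue.pop(0)
        for t in graph.neighbors[lattice.spot_id[i]]:
            j = pos[t]
            if not in_zone[j] and in_zone.sum() < target:
                in_zone[j] = True
                queue.append(j)
    return in_zone


def plant_colocalization(cfg: SimConfig, lattice: SpotLattice, niches: dict | None = None,
                         rng=None) -> ColocTruth:
    """Plant the joint-presence / high-ratio structure.

    Inside a contiguous zone the joint presence of the two focal types has
    its odds multiplied by ``coloc_odds`` and the designated isoform pair
    is drawn so its ratio exceeds 15 with probability ~0.98; outside, the
    types are independent Bernoulli(``base_presence``) and the ratio
    concentrates at or below 1.  Marker counts are positive exactly where
    the corresponding type is planted present.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = lattice.n_spots
    in_zone = _grow_zone(lattice, cfg.ratio_zone_fraction, rng)

    p0 = cfg.base_presence
    base = np.array([p0 * p0, p0 * (1 - p0), (1 - p0) * p0, (1 - p0) * (1 - p0)])
    pmf_out = base / base.sum()
    boosted = base.copy()
    boosted[0] *= cfg.coloc_odds
    pmf_in = boosted / boosted.sum()
    u = rng.random(n)
    cum_out = np.cumsum(pmf_out)
    cum_in = np.cumsum(pmf_in)
    cell = np.where(in_zone, np.searchsorted(cum_in, u), np.searchsorted(cum_out, u))
    cell = np.minimum(cell, 3)
    present_a = np.isin(cell, (0, 1))
    present_b = np.isin(cell, (0, 2))

    count_b = np.where(
        in_zone,
        1 + rng.poisson(cfg.zone_denom_extra_mean, n),
        rng.poisson(cfg.out_zone_denom_mean, n),
    ).astype(np.int64)
    count_a = np.where(
        in_zone,
        rng.poisson(cfg.zone_ratio_mean * np.maximum(count_b, 1)),
        rng.poisson(cfg.out_zone_num_mean, n),
    ).astype(np.int64)

    spots = pd.Index([str(s) for s in lattice.spot_id], name="spot_id")
    marker = {}
    for g in cfg.tex_markers:
        marker[g] = np.where(present_a, 1 + rng.poisson(1.0, n), 0).astype(np.int64)
    for g in cfg.tam_markers:
        marker[g] = np.where(present_b, 1 + rng.poisson(1.0, n), 0).astype(np.int64)

    return ColocTruth(
        presence=pd.DataFrame({"present_a": present_a, "present_b": present_b}, index=spots),
        pair_counts=pd.DataFrame({"count_a": count_a, "count_b": count_b}, index=spots),
        zone=pd.Series(in_zone, index=spots, name="in_zone"),
        marker_counts=pd.DataFrame(marker, index=spots),
    )


def _plan_patterns(plan: pd.DataFrame, cfg: SimConfig, rng) -> pd.Series:
    names = list(cfg.pattern_mix)
    probs = np.array([cfg.pattern_mix[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    picks = rng.choice(len(names), size=len(plan), p=probs)
    return pd.Series([names[i] for i in picks], index=plan["isoform_id"], name="pattern")


def simulate_sample_trio(cfg: SimConfig, lattice: SpotLattice, niches: dict,
                         plan: pd.DataFrame, after_iso: CountMatrix, rng) -> tuple:
    """Before / AfterLN isoform matrices implied by planted expression patterns.

    The base draw is the After-treatment tumor.  Per-sample mean
    multipliers encode the planted pattern: resistance halves the Before
    mean by ``pattern_fc`` (so After/Before rises), treatment_target
    raises it; metastasis positive/negative scale the AfterLN mean.
    """
    patterns = _plan_patterns(plan, cfg, rng)
    fc = cfg.pattern_fc
    before_mult = patterns.map(
        {"resistance": 1 / fc, "treatment_target": fc}).fillna(1.0)
    ln_mult = patterns.map(
        {"metastasis_positive": fc, "metastasis_negative": 1 / fc}).fillna(1.0)
    niche_idx = np.array([niches[s] for s in lattice.spot_id])
    spots = [str(s) for s in lattice.spot_id]
    iso2gene = dict(zip(plan["isoform_id"], plan["gene_id"]))

    def _mat(mult):
        counts = _draw_iso_counts(plan, niche_idx, cfg, rng, mean_mult=mult)
        return CountMatrix(spots=spots, features=plan["isoform_id"].tolist(),
                           counts=counts, level="isoform", iso2gene=iso2gene)

    return _mat(before_mult), _mat(ln_mult), patterns


def _append_features(matrix: CountMatrix, extra: pd.DataFrame, level: str,
                     iso2gene: dict | None = None) -> CountMatrix:
    extra = extra.loc[matrix.spots]
    counts = sp.hstack([matrix.counts, sp.csr_matrix(extra.to_numpy(dtype=np.int64))]).tocsr()
    return CountMatrix(
        spots=matrix.spots, features=matrix.features + list(extra.columns),
        counts=counts, level=level,
        iso2gene=(dict(matrix.iso2gene or {}) | (iso2gene or {})) if level == "isoform" else None,
    )


def generate_dataset(cfg: SimConfig, outdir) -> GroundTruth:
    """Generate and write a complete synthetic bundle; return its truth.

    The bundle uses exactly the on-disk formats :mod:`isoniche.io` reads:
    gene and isoform MTX triples, tissue positions CSV, iso2gene TSV, a
    deconvolved cell-fraction TSV consistent with the planted presence, the
    ground-truth tables, and a machine-readable config echo.  The same
    config (seed included) yields a byte-identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    r_niche, r_counts, r_coloc, r_trio, r_frac = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    lattice = build_hex_lattice(cfg.n_rows, cfg.n_cols)
    niche_seed = int(r_niche.integers(0, 2**31 - 1))
    niches = plant_niches(lattice, cfg.n_niches, niche_seed)
    gene_m, iso_m, plan = simulate_counts(cfg, lattice, niches, rng=r_counts)
    coloc = plant_colocalization(cfg, lattice, niches, rng=r_coloc)

    # Fold the focal-pair isoforms and the marker genes into the matrices.
    iso_a, iso_b = cfg.ratio_pair
    pair = coloc.pair_counts.rename(columns={"count_a": iso_a, "count_b": iso_b})
    iso_full = _append_features(iso_m, pair, "isoform",
                                {iso_a: cfg.ratio_gene, iso_b: cfg.ratio_gene})
    gene_extra = coloc.marker_counts.copy()
    gene_extra[cfg.ratio_gene] = (
        coloc.pair_counts["count_a"] + coloc.pair_counts["count_b"]
    )
    gene_full = _append_features(gene_m, gene_extra, "gene")

    write_positions(lattice, outdir / "tissue_positions.csv", header=True)
    write_counts(gene_full, outdir / "gene_matrix.mtx", outdir / "gene_features.tsv",
                 outdir / "barcodes.tsv")
    write_counts(iso_full, outdir / "iso_matrix.mtx", outdir / "iso_features.tsv",
                 outdir / "iso_barcodes.tsv")
    pd.Series(iso_full.iso2gene).rename_axis("isoform_id").to_csv(
        outdir / "iso2gene.tsv", sep="\t", header=False)

    # Deconvolution-style fractions consistent with planted presence at the
    # conventional 0.6 cutoff.
    u = r_frac.random((lattice.n_spots, 2))
    frac = pd.DataFrame(
        {
            "CD8_CXCL13_Tex": np.where(coloc.presence["present_a"],
                                       0.6 + 0.4 * u[:, 0], 0.59 * u[:, 0]),
            "C1QC_TAM": np.where(coloc.presence["present_b"],
                                 0.6 + 0.4 * u[:, 1], 0.59 * u[:, 1]),
        },
        index=coloc.presence.index,
    )
    frac.round(6).to_csv(outdir / "cell_fractions.tsv", sep="\t")

    pattern = pd.Series("none", index=plan["isoform_id"], name="pattern")
    if cfg.emit_trio:
        before_m, ln_m, pattern = simulate_sample_trio(cfg, lattice, niches, plan,
                                                       iso_m, rng=r_trio)
        for name, m in (("before", before_m), ("after_ln", ln_m)):
            sub = outdir / name
            sub.mkdir(exist_ok=True)
            write_counts(m, sub / "iso_matrix.mtx", sub / "iso_features.tsv",
                         sub / "iso_barcodes.tsv")

    truth_tbl = plan.set_index("isoform_id")[["gene_id", "class"]].copy()
    truth_tbl["support"] = [",".join(map(str, s)) for s in plan["support"]]
    truth_tbl["pattern"] = pattern
    truth_tbl.to_csv(outdir / "truth_isoforms.tsv", sep="\t")
    spot_truth = pd.DataFrame(
        {
            "niche": [niches[s] for s in coloc.presence.index],
            "present_a": coloc.presence["present_a"].astype(int),
            "present_b": coloc.presence["present_b"].astype(int),
            "in_zone": coloc.zone.astype(int),
        },
        index=coloc.presence.index,
    )
    spot_truth.to_csv(outdir / "truth_spots.tsv", sep="\t")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return GroundTruth(
        niches=niches,
        spatial_class=plan.set_index("isoform_id")["class"],
        support=dict(zip(plan["isoform_id"], plan["support"])),
        pattern=pattern,
        presence=coloc.presence,
        zone=coloc.zone,
        config=cfg,
    )
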