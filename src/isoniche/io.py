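"""Reading, writing, QC and normalization of Visium-style spatial data.

The on-disk dialects are the Space Ranger ones: a ``tissue_positions`` CSV
(headerless v1 or headered v2), a Matrix Market count matrix with sidecar
``features.tsv`` / ``barcodes.tsv`` lists, and a two-column isoform-to-gene
TSV when the matrix is at isoform resolution.

Spot-level QC follows the common short-read convention: a spot is dropped
when it detects fewer than ``min_genes_per_spot`` genes (count > 0) or when
its mitochondrial UMI fraction exceeds ``max_mito_fraction``.  Both bounds
are strict, mirroring the usual "<1000" / ">5%" phrasing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import ConfigError, FormatError, IntegrityError

__all__ = [
    "SpotLattice",
    "CountMatrix",
    "QCConfig",
    "read_positions",
    "write_positions",
    "read_counts",
    "write_counts",
    "read_iso2gene",
    "qc_filter_spots",
    "log_normalize",
]

_POSITIONS_COLUMNS = ("barcode", "in_tissue", "array_row", "array_col", "px_row", "px_col")


@dataclass
class SpotLattice:
    """Spot identities with Visium array and pixel coordinates.

    ``pixel_only`` is set when the array coordinates do not form a consistent
    staggered (hexagonal) grid — i.e. the parity of ``array_row + array_col``
    varies across spots — in which case neighborhood structure must be
    derived from pixel distances instead of array adjacency.
    """

    spot_id: np.ndarray
    in_tissue: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    px_x: np.ndarray
    px_y: np.ndarray
    pixel_only: bool = False

    def __post_init__(self) -> None:
        self.spot_id = np.asarray(self.spot_id, dtype=object)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        self.array_row = np.asarray(self.array_row, dtype=np.int64)
        self.array_col = np.asarray(self.array_col, dtype=np.int64)
        self.px_x = np.asarray(self.px_x, dtype=float)
        self.px_y = np.asarray(self.px_y, dtype=float)
        ids = pd.Index(self.spot_id)
        if ids.has_duplicates:
            dup = ids[ids.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate spot barcodes: {dup[:5]}")
        if len(self.spot_id) and not self.pixel_only:
            parity = (self.array_row + self.array_col) % 2
            if len(np.unique(parity)) > 1:
                self.pixel_only = True
            else:
                rc = pd.MultiIndex.from_arrays([self.array_row, self.array_col])
                if rc.has_duplicates:
                    raise IntegrityError("two spots share the same (array_row, array_col)")

    @property
    def n_spots(self) -> int:
        return len(self.spot_id)

    def subset(self, spot_ids) -> "SpotLattice":
        """Restrict the lattice to ``spot_ids``, preserving their order."""
        pos = pd.Index(self.spot_id).get_indexer(list(spot_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(spot_ids, pos) if p < 0]
            raise KeyError(f"spots not in lattice: {missing[:5]}")
        return SpotLattice(
            self.spot_id[pos], self.in_tissue[pos], self.array_row[pos],
            self.array_col[pos], self.px_x[pos], self.px_y[pos],
            pixel_only=self.pixel_only,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.spot_id,
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.array_row,
                "array_col": self.array_col,
                "px_row": self.px_y,
                "px_col": self.px_x,
            }
        )


@dataclass
class CountMatrix:
    """Spots x features counts at gene or isoform resolution.

    ``counts`` is CSR with rows = spots.  Raw matrices are non-negative
    integers; after :func:`log_normalize` the values are real and
    ``normalized`` is set.
    """

    spots: list
    features: list
    counts: sp.csr_matrix
    level: str = "gene"
    iso2gene: dict | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("gene", "isoform"):
            raise ConfigError(f"level must be 'gene' or 'isoform', got {self.level!r}")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.spots), len(self.features)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.spots)} spots x {len(self.features)} features"
            )
        if not self.normalized:
            data = self.counts.data
            if data.size and (data < 0).any():
                raise IntegrityError("negative count entry")
            if data.size and not np.allclose(data, np.round(data)):
                raise IntegrityError("non-integer count entry in raw matrix")
            self.counts = self.counts.astype(np.int64)
        if self.level == "isoform":
            if self.iso2gene is None:
                raise ConfigError("isoform-level matrix requires an iso2gene map")
            missing = [f for f in self.features if f not in self.iso2gene]
            if missing:
                raise IntegrityError(f"isoforms missing from iso2gene: {missing[:5]}")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.features.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def column(self, feature_id: str) -> np.ndarray:
        """Dense per-spot vector for one feature."""
        return np.asarray(self.counts[:, self.feature_index(feature_id)].todense()).ravel()

    def subset_spots(self, spot_ids) -> "CountMatrix":
        pos = pd.Index(self.spots, dtype=object).get_indexer(list(spot_ids))
        if (pos < 0).any():
            raise KeyError("requested spots not present in matrix")
        return replace(self, spots=list(spot_ids), counts=self.counts[pos])

    def genes_of(self) -> pd.Series:
        """Per-feature gene id (identity at gene level)."""
        if self.level == "gene":
            return pd.Series(self.features, index=self.features)
        return pd.Series([self.iso2gene[f] for f in self.features], index=self.features)


@dataclass
class QCConfig:
    """Spot QC thresholds.

    min_genes_per_spot : spots detecting fewer genes are removed (strict <).
    max_mito_fraction  : spots with a larger mitochondrial UMI share are
                         removed (strict >).
    mito_prefix        : feature-name prefix identifying mitochondrial genes.
    """

    min_genes_per_spot: int = 1000
    max_mito_fraction: float = 0.05
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ConfigError("max_mito_fraction must be in [0, 1]")
        if self.min_genes_per_spot < 0:
            raise ConfigError("min_genes_per_spot must be >= 0")


def read_positions(path) -> SpotLattice:
    """Parse a Space Ranger tissue positions CSV into a :class:`SpotLattice`.

    Both dialects are accepted: the headerless v1 file and the headered v2
    file (``barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,...``).
    The header is auto-detected from the first field of the first row.
    """
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and row[0].strip().lower() == "barcode":
                continue  # v2 header line
            if len(row) != 6:
                raise FormatError(f"{path.name} line {lineno}: expected 6 fields, got {len(row)}")
            try:
                barcode = row[0].strip()
                in_tissue = int(row[1])
                r, c = int(row[2]), int(row[3])
                px_row, px_col = float(row[4]), float(row[5])
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from None
            if in_tissue not in (0, 1):
                raise FormatError(f"{path.name} line {lineno}: in_tissue must be 0 or 1")
            if r < 0 or c < 0:
                raise FormatError(f"{path.name} line {lineno}: negative array coordinate")
            rows.append((barcode, in_tissue, r, c, px_row, px_col))
    if not rows:
        raise FormatError(f"{path.name}: no spot rows")
    barcode, in_tissue, r, c, px_row, px_col = map(np.array, zip(*rows))
    # Space Ranger stores (row, col) pixel order; expose x = col, y = row.
    return SpotLattice(barcode, in_tissue.astype(bool), r, c, px_x=px_col, px_y=px_row)


def write_positions(lattice: SpotLattice, path, header: bool = False) -> None:
    df = lattice.to_frame()
    if header:
        df = df.rename(
            columns={"px_row": "pxl_row_in_fullres", "px_col": "pxl_col_in_fullres"}
        )
    df.to_csv(path, index=False, header=header)


def read_iso2gene(path) -> dict:
    """Two-column TSV (isoform_id, gene_id) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["isoform_id", "gene_id"], dtype=str)
    if df["isoform_id"].duplicated().any():
        dup = df.loc[df["isoform_id"].duplicated(), "isoform_id"].tolist()
        raise IntegrityError(f"isoform mapped to more than one gene: {dup[:5]}")
    return dict(zip(df["isoform_id"], df["gene_id"]))


def read_counts(mtx_path, features_path, barcodes_path, level: str = "gene",
                iso2gene: Mapping | str | Path | None = None) -> CountMatrix:
    """Load an MTX + features + barcodes triple (features x barcodes on disk).

    The matrix is stored features-by-barcodes as Cell Ranger writes it and is
    transposed to spots-by-features in memory.
    """
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    mat = scipy.io.mmread(str(mtx_path))
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"MTX dimensions {mat.shape} do not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    if isinstance(iso2gene, (str, Path)):
        iso2gene = read_iso2gene(iso2gene)
    counts = sp.csr_matrix(mat.T)
    return CountMatrix(spots=barcodes, features=features, counts=counts,
                       level=level, iso2gene=dict(iso2gene) if iso2gene else None)


def write_counts(m: CountMatrix, mtx_path, features_path, barcodes_path) -> None:
    """Write the features x barcodes MTX triple (inverse of :func:`read_counts`)."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(m.counts.T.astype(np.int64)))
    pd.Series(m.features).to_csv(features_path, sep="\t", index=False, header=False)
    pd.Series(m.spots).to_csv(barcodes_path, sep="\t", index=False, header=False)


def qc_filter_spots(m: CountMatrix, cfg: QCConfig | None = None):
    """Remove low-quality spots from a gene-level matrix.

    Returns ``(filtered_matrix, removal_log)`` where the log is a DataFrame
    with one row per (spot, reason); a spot failing both rules appears twice.
    Surviving spot order is preserved.  Filtering is idempotent.
    """
    cfg = cfg or QCConfig()
    if m.level != "gene":
        raise ConfigError("QC operates on the gene-level matrix")
    if m.normalized:
        raise ConfigError("QC operates on raw counts; normalize afterwards")
    X = m.counts
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    is_mito = np.array([f.startswith(cfg.mito_prefix) for f in m.features], dtype=bool)
    mito = np.asarray(X[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(len(m.spots))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 0.0)

    low = n_genes < cfg.min_genes_per_spot
    high_mito = mito_frac > cfg.max_mito_fraction
    records = []
    for i, spot in enumerate(m.spots):
        if low[i]:
            records.append((spot, "low_gene_count"))
        if high_mito[i]:
            records.append((spot, "high_mito"))
    log = pd.DataFrame(records, columns=["spot_id", "reason"])
    keep = ~(low | high_mito)
    if not keep.any():
        import warnings

        warnings.warn("QC removed every spot", stacklevel=2)
    kept = [s for s, k in zip(m.spots, keep) if k]
    return replace(m, spots=kept, counts=X[keep]), log


def log_normalize(m: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Library-size log-normalization: ln(1 + scale * count / spot_total).

    Zeros map to zeros, so the sparsity pattern is preserved exactly.  Spots
    with zero total are a QC failure and raise.
    """
    if m.normalized:
        raise ConfigError("matrix is already normalized")
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        bad = [s for s, t in zip(m.spots, totals) if t <= 0]
        raise IntegrityError(
            f"spots with zero total count (run QC first): {bad[:5]}"
        )
    X = m.counts.tocoo().astype(float)
    X.data = np.log1p(scale * X.data / totals[X.row])
    out = replace(m, counts=X.tocsr(), normalized=True)
    return out
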