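"""Spatial isoform classes, expression-pattern classes, and the
nonmajority differential-splicing screen.

Spatial classes (per isoform, relative to its gene and the niche map):

    single        the gene's only isoform
    multi_all     detected in every niche
    multi_one     detected in exactly one niche
    multi_others  detected in >= 2 niches but not all
    undetected    detected in no niche (excluded from the four-way tally)

"Detected in a niche" means a positive count in at least
``detection_min_spots`` spots of that niche (default 1); the threshold is a
free choice that shifts the class proportions, so it is exposed.

Expression patterns contrast mean expression across a Before-treatment
tumor, an After-treatment tumor, and a metastatic lymph node (AfterLN):
metastasis positive/negative from AfterLN vs After, resistance/treatment
target from After vs Before.  An isoform can satisfy several contrasts; all
qualifying labels are kept and the headline label is the one with the
largest absolute log fold change.

The differential screen mirrors the Seurat FindMarkers recipe (Wilcoxon
rank-sum niche vs rest, logfc.threshold 0.25, min.pct 0.1, Bonferroni
<= 0.05) and then drops each gene's majority isoform — the one with the
highest bulk raw count — so that only alternate isoforms can pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from ._errors import ConfigError, IntegrityError
from .io import CountMatrix, log_normalize

__all__ = [
    "DSConfig",
    "SPATIAL_CLASSES",
    "EXPRESSION_PATTERNS",
    "classify_spatial",
    "classify_pattern",
    "class_distribution",
    "wilcoxon_rank_sum",
    "differential_splicing",
    "bonferroni",
]

SPATIAL_CLASSES = ("single", "multi_all", "multi_one", "multi_others")
EXPRESSION_PATTERNS = (
    "metastasis_negative",
    "metastasis_positive",
    "resistance",
    "treatment_target",
    "none",
)


@dataclass
class DSConfig:
    """Thresholds for the differential-splicing screen and pattern classes."""

    logfc_threshold: float = 0.25
    min_pct: float = 0.1
    alpha: float = 0.05
    detection_min_spots: int = 1
    pattern_fc_threshold: float = 1.5

    def __post_init__(self) -> None:
        for name in ("logfc_threshold", "min_pct", "alpha", "pattern_fc_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.detection_min_spots < 1:
            raise ConfigError("detection_min_spots must be >= 1")
        if self.pattern_fc_threshold <= 1:
            raise ConfigError("pattern_fc_threshold must be > 1")


def _niche_groups(spots, niches) -> dict:
    """niche label -> boolean spot mask, in sorted label order."""
    labels = []
    for s in spots:
        if s not in niches:
            raise IntegrityError(f"spot {s!r} has no niche label")
        labels.append(niches[s])
    labels = np.asarray(labels, dtype=object)
    return {lab: labels == lab for lab in sorted(set(labels.tolist()), key=str)}


def classify_spatial(iso_matrix: CountMatrix, niches, detection_min_spots: int = 1) -> pd.DataFrame:
    """Assign each isoform its spatial class.

    Returns a DataFrame indexed by isoform id with columns ``gene_id``,
    ``n_isoforms`` (of the gene), ``support`` (tuple of niches where
    detected), ``n_niches_detected`` and ``spatial_class``.
    """
    if iso_matrix.level != "isoform":
        raise ConfigError("classify_spatial needs an isoform-level matrix")
    groups = _niche_groups(iso_matrix.spots, niches)
    K = len(groups)
    X = iso_matrix.counts
    detected = {}
    for lab, mask in groups.items():
        n_pos = np.asarray((X[mask] > 0).sum(axis=0)).ravel()
        detected[lab] = n_pos >= detection_min_spots
    genes = iso_matrix.genes_of()
    iso_per_gene = genes.groupby(genes).size()
    rows = []
    for j, iso in enumerate(iso_matrix.features):
        support = tuple(lab for lab in groups if detected[lab][j])
        n_iso = int(iso_per_gene[genes[iso]])
        if not support:
            cls = "undetected"
        elif n_iso == 1:
            cls = "single"
        elif len(support) == K:
            cls = "multi_all"
        elif len(support) == 1:
            cls = "multi_one"
        else:
            cls = "multi_others"
        rows.append((iso, genes[iso], n_iso, support, len(support), cls))
    return pd.DataFrame(
        rows,
        columns=["isoform_id", "gene_id", "n_isoforms", "support",
                 "n_niches_detected", "spatial_class"],
    ).set_index("isoform_id")


def class_distribution(classes: pd.DataFrame) -> dict:
    """Counts and percentages per spatial class over detected isoforms."""
    det = classes[classes["spatial_class"] != "undetected"]
    counts = det["spatial_class"].value_counts().reindex(SPATIAL_CLASSES, fill_value=0)
    total = int(counts.sum())
    return {
        "n_detected": total,
        "n_undetected": int((classes["spatial_class"] == "undetected").sum()),
        "counts": {k: int(v) for k, v in counts.items()},
        "percent": {k: (100.0 * v / total if total else float("nan")) for k, v in counts.items()},
    }


def _mean_expression(m: CountMatrix) -> pd.Series:
    vals = np.asarray(m.counts.mean(axis=0)).ravel()
    return pd.Series(vals, index=m.features)


def classify_pattern(matrices: dict, cfg: DSConfig | None = None) -> pd.DataFrame:
    """Classify isoforms by their cross-sample expression pattern.

    ``matrices`` maps the keys ``before``, ``after``, ``after_ln`` to
    normalized isoform matrices on a shared isoform space (isoforms absent
    from a sample count as zero).  For each isoform:

    * metastasis_positive  mean(AfterLN)/mean(After) >= threshold
    * metastasis_negative  mean(AfterLN)/mean(After) <= 1/threshold
    * resistance           mean(After)/mean(Before)  >= threshold
    * treatment_target     mean(After)/mean(Before)  <= 1/threshold

    A contrast whose two means are both zero yields no label.  All
    qualifying labels are reported; ``pattern`` holds the headline label
    (largest |log fold change|), or "none".
    """
    cfg = cfg or DSConfig()
    required = {"before", "after", "after_ln"}
    if set(matrices) != required:
        raise ConfigError(f"matrices must have keys {sorted(required)}")
    means = {k: _mean_expression(m) for k, m in matrices.items()}
    features = sorted(set().union(*[m.index for m in means.values()]))
    aligned = {k: v.reindex(features, fill_value=0.0) for k, v in means.items()}

    def _fc(num, den):
        if num == 0 and den == 0:
            return np.nan
        if den == 0:
            return np.inf
        return num / den

    rows = []
    for iso in features:
        met_fc = _fc(aligned["after_ln"][iso], aligned["after"][iso])
        res_fc = _fc(aligned["after"][iso], aligned["before"][iso])
        labels = []
        if not np.isnan(met_fc):
            if met_fc >= cfg.pattern_fc_threshold:
                labels.append(("metastasis_positive", abs(np.log(met_fc))))
            elif met_fc <= 1.0 / cfg.pattern_fc_threshold:
                labels.append(("metastasis_negative",
                               abs(np.log(met_fc)) if met_fc > 0 else np.inf))
        if not np.isnan(res_fc):
            if res_fc >= cfg.pattern_fc_threshold:
                labels.append(("resistance", abs(np.log(res_fc))))
            elif res_fc <= 1.0 / cfg.pattern_fc_threshold:
                labels.append(("treatment_target",
                               abs(np.log(res_fc)) if res_fc > 0 else np.inf))
        labels.sort(key=lambda kv: -kv[1])
        rows.append(
            (iso, met_fc, res_fc, tuple(k for k, _ in labels),
             labels[0][0] if labels else "none")
        )
    return pd.DataFrame(
        rows, columns=["isoform_id", "metastasis_fc", "resistance_fc", "labels", "pattern"]
    ).set_index("isoform_id")


def wilcoxon_rank_sum(x, y, exact_max_n: int = 12):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks handle ties.  When the pooled size is at most ``exact_max_n``
    the null distribution of the rank sum is enumerated exactly
    (conditional on the observed tie pattern); otherwise the normal
    approximation with tie-corrected variance and a continuity correction
    is used.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    N = nx + ny
    ranks = rankdata(pooled, method="average")
    W = float(ranks[:nx].sum())
    mu = nx * (N + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return W, 1.0

    if N <= exact_max_n:
        dev = abs(W - mu)
        hits = 0
        total = comb(N, nx)
        for idx in combinations(range(N), nx):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        return W, hits / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = nx * ny / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return W, 1.0
    z = (W - mu - np.sign(W - mu) * 0.5) / np.sqrt(var)
    p = float(2.0 * _norm.sf(abs(z)))
    return W, min(p, 1.0)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)


def differential_splicing(iso_matrix: CountMatrix, niches, cfg: DSConfig | None = None) -> pd.DataFrame:
    """Niche-vs-rest differential isoform usage screen.

    Takes RAW isoform counts (normalized internally): the majority-isoform
    flag is defined on raw bulk counts while the test statistics run on
    log-normalized values.  For every niche with >= 3 spots, every isoform
    of a gene with >= 2 isoforms is tested niche vs rest with the Wilcoxon
    rank-sum.  Per test:

    * logFC   ln(mean(expm1 v_in) + 1) - ln(mean(expm1 v_out) + 1)
    * pct_in / pct_out   detection fractions (count > 0)
    * p_adj   Bonferroni over all tests performed in this run
    * majority   the gene's top bulk-count isoform (ties: lexicographic)
    * pass   not majority, p_adj <= alpha, |logFC| >= logfc_threshold,
             max(pct_in, pct_out) >= min_pct
    """
    cfg = cfg or DSConfig()
    if iso_matrix.level != "isoform":
        raise ConfigError("differential_splicing needs an isoform-level matrix")
    if iso_matrix.normalized:
        raise ConfigError("pass raw counts; normalization happens internally")
    norm = log_normalize(iso_matrix)
    groups = _niche_groups(iso_matrix.spots, niches)

    genes = iso_matrix.genes_of()
    bulk = pd.Series(
        np.asarray(iso_matrix.counts.sum(axis=0)).ravel(), index=iso_matrix.features
    )
    majority = set()
    for gene, members in bulk.groupby(genes):
        top = members[members == members.max()]
        majority.add(sorted(top.index)[0])  # ties -> lexicographically first
    multi = genes.groupby(genes).transform("size") >= 2
    test_features = [f for f in iso_matrix.features if multi[f]]
    feat_pos = {f: j for j, f in enumerate(iso_matrix.features)}

    Xn = norm.counts.toarray()
    det = np.asarray((iso_matrix.counts > 0).todense())
    rows = []
    for lab, mask in groups.items():
        n_in = int(mask.sum())
        if n_in < 3 or (len(mask) - n_in) < 3:
            warnings.warn(f"niche {lab!r}: fewer than 3 spots on one side, tests skipped",
                          stacklevel=2)
            continue
        for f in test_features:
            j = feat_pos[f]
            v_in = Xn[mask, j]
            v_out = Xn[~mask, j]
            logfc = float(np.log(np.expm1(v_in).mean() + 1) - np.log(np.expm1(v_out).mean() + 1))
            pct_in = float(det[mask, j].mean())
            pct_out = float(det[~mask, j].mean())
            _, p = wilcoxon_rank_sum(v_in, v_out)
            rows.append((f, genes[f], lab, logfc, pct_in, pct_out, p, f in majority))
    res = pd.DataFrame(
        rows,
        columns=["isoform_id", "gene_id", "niche", "log_fc", "pct_in", "pct_out",
                 "pvalue", "is_majority"],
    )
    if res.empty:
        res["p_adj"] = res["pass"] = pd.Series(dtype=float)
        return res
    res["p_adj"] = bonferroni(res["pvalue"].to_numpy())
    res["pass"] = (
        ~res["is_majority"]
        & (res["p_adj"] <= cfg.alpha)
        & (res["log_fc"].abs() >= cfg.logfc_threshold)
        & (res[["pct_in", "pct_out"]].max(axis=1) >= cfg.min_pct)
    )
    return res
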