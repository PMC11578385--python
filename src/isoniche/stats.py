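"""Isoform-ratio grouping and the association tests, from first principles.

Spots are grouped by the expression ratio of two isoforms of one gene
(the motivating case is CD74-202 / CD74-201):

    High    ratio > 15
    Medium  1 < ratio <= 15
    Low     ratio <= 1           (denominator > 0)
    Others  denominator = 0      (ratio undefined)

Both thresholds are inclusive on the lower group.  The tests used to relate
grouping to neighborhood enrichment — Pearson's chi-square and the unpaired
two-tailed t-test (Student pooled-variance by default, Welch optional) —
are implemented directly; scipy supplies only the distribution tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import t as _t_dist

from ._errors import ConfigError, IntegrityError

__all__ = [
    "TestResult",
    "compute_ratio",
    "assign_groups",
    "chi_square_test",
    "t_test_unpaired",
    "association_report",
    "RATIO_GROUPS",
]

RATIO_GROUPS = ("Low", "Medium", "High", "Others")

_P_FLOOR = float(np.nextafter(0, 1))  # smallest positive subnormal double


@dataclass
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    df: float
    pvalue: float
    effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def compute_ratio(iso_matrix, iso_a: str, iso_b: str) -> pd.DataFrame:
    """Per-spot expression ratio of two isoforms (NaN where denominator = 0).

    Ratios are taken on the raw counts: within a spot the library size
    cancels, so the raw and library-size-normalized ratios coincide.
    """
    a = iso_matrix.column(iso_a).astype(float)
    b = iso_matrix.column(iso_b).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.nan)
    return pd.DataFrame(
        {"count_a": a, "count_b": b, "ratio": ratio},
        index=pd.Index(iso_matrix.spots, name="spot_id"),
    )


def assign_groups(ratios: pd.DataFrame | pd.Series, high: float = 15.0, low: float = 1.0) -> pd.DataFrame:
    """Assign every spot to exactly one of High / Medium / Low / Others.

    Boundary semantics: ratio exactly ``high`` is Medium and exactly ``low``
    is Low (both thresholds inclusive downward); an undefined ratio
    (denominator zero) is Others.
    """
    if not (high > low > 0):
        raise ConfigError(f"thresholds must satisfy high > low > 0, got {high}, {low}")
    if isinstance(ratios, pd.Series):
        df = ratios.to_frame("ratio").copy()
    else:
        df = ratios.copy()
    r = df["ratio"].to_numpy(dtype=float)
    group = np.where(
        np.isnan(r), "Others", np.where(r > high, "High", np.where(r > low, "Medium", "Low"))
    )
    df["group"] = pd.Categorical(group, categories=list(RATIO_GROUPS))
    return df


def chi_square_test(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Rows/columns with a zero margin are dropped with a warning; the test
    needs at least a 2 x 2 table afterwards.  ``correction`` applies the
    Yates continuity correction (2 x 2 only); off by default.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ConfigError("table must be at least 2 x 2")
    if (O < 0).any():
        raise IntegrityError("negative cell count")
    row_keep = O.sum(axis=1) > 0
    col_keep = O.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table", stacklevel=2)
        O = O[row_keep][:, col_keep]
    r, c = O.shape
    if r < 2 or c < 2:
        raise IntegrityError("table degenerate after dropping zero margins")
    N = O.sum()
    if N <= 0:
        raise IntegrityError("grand total must be positive")
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / N
    diff = np.abs(O - E)
    if correction and r == 2 and c == 2:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / E).sum())
    dof = (r - 1) * (c - 1)
    p = float(_chi2_dist.sf(stat, dof))
    return TestResult(stat, float(dof), min(p, 1.0), effect={"observed": O, "expected": E})


def t_test_unpaired(x, y, variant: str = "student") -> TestResult:
    """Unpaired two-tailed t-test.

    variant="student" uses the pooled variance with df = n_x + n_y - 2;
    variant="welch" uses per-group variances with Satterthwaite df.
    Degenerate inputs: zero variance with equal means gives t = 0, p = 1;
    zero variance with unequal means reports an infinite statistic and a
    p-value at the smallest representable positive float.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if variant == "student":
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    elif variant == "welch":
        se2x, se2y = vx / nx, vy / ny
        se = np.sqrt(se2x + se2y)
        if se > 0:
            df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
        else:
            df = nx + ny - 2
    else:
        raise ValueError("variant must be 'student' or 'welch'")
    effect = {"mean_x": mx, "mean_y": my, "n_x": nx, "n_y": ny}
    if se == 0:
        if mx == my:
            return TestResult(0.0, float(df), 1.0, effect)
        stat = np.inf if mx > my else -np.inf
        return TestResult(float(stat), float(df), _P_FLOOR, effect)
    t = (mx - my) / se
    p = float(2.0 * _t_dist.sf(abs(t), df))
    return TestResult(float(t), float(df), min(p, 1.0), effect)


def association_report(grouping: pd.DataFrame, enrichment: pd.DataFrame) -> dict:
    """Relate ratio groups to neighborhood enrichment on a common spot set.

    Components (empty groups are skipped with a warning):

    1. ``contingency`` / ``chi_square`` — Low/Medium/High x enrichment-spot
       status (Others excluded) with Pearson's chi-square, plus every 2 x 2
       sub-table's test under ``chi_square_2x2``.
    2. ``score_t_tests`` — pairwise Student t-tests of the enrichment score
       across the three ratio groups.
    3. ``ratio_t_test`` — ratio in enrichment spots vs other spots, on
       spots with a defined ratio.
    """
    common = grouping.index.intersection(enrichment.index)
    if len(common) == 0:
        raise IntegrityError("grouping and enrichment share no spots")
    g = grouping.loc[common]
    e = enrichment.loc[common]
    report: dict = {"n_spots": int(len(common))}

    ordered = ["Low", "Medium", "High"]
    present = [lvl for lvl in ordered if (g["group"] == lvl).sum() > 0]
    skipped = [lvl for lvl in ordered if lvl not in present]
    if skipped:
        warnings.warn(f"empty ratio groups skipped: {skipped}", stacklevel=2)
    report["group_sizes"] = {lvl: int((g["group"] == lvl).sum()) for lvl in ordered}
    report["group_sizes"]["Others"] = int((g["group"] == "Others").sum())

    tab = pd.crosstab(
        g["group"].cat.set_categories(present), e["is_enrichment_spot"]
    ).reindex(index=present, columns=[False, True], fill_value=0)
    report["contingency"] = tab
    if len(present) >= 2 and (tab.to_numpy().sum(axis=0) > 0).sum() >= 2:
        res = chi_square_test(tab.to_numpy())
        report["chi_square"] = res
        report["chi_square_2x2"] = {}
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                sub = tab.loc[[a, b]].to_numpy()
                if (sub.sum(axis=0) > 0).all() and (sub.sum(axis=1) > 0).all():
                    report["chi_square_2x2"][f"{a}_vs_{b}"] = chi_square_test(sub)

    report["score_t_tests"] = {}
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            sa = e.loc[g["group"] == a, "score"].to_numpy(dtype=float)
            sb = e.loc[g["group"] == b, "score"].to_numpy(dtype=float)
            if len(sa) >= 2 and len(sb) >= 2:
                report["score_t_tests"][f"{a}_vs_{b}"] = t_test_unpaired(sa, sb)

    defined = g["ratio"].notna()
    in_spot = e["is_enrichment_spot"].astype(bool)
    r_in = g.loc[defined & in_spot, "ratio"].to_numpy(dtype=float)
    r_out = g.loc[defined & ~in_spot, "ratio"].to_numpy(dtype=float)
    if len(r_in) >= 2 and len(r_out) >= 2:
        report["ratio_t_test"] = t_test_unpaired(r_in, r_out)
    else:
        warnings.warn("too few spots with defined ratio for the enrichment-spot t-test",
                      stacklevel=2)
    return report
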