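"""Group-comparison statistics for subtype characterization.

Thin, validated wrappers around the classical tests used to profile
subtypes: Pearson chi-square on contingency tables (no continuity
correction), partial Pearson correlation via OLS residuals, one-way ANOVA
with Tukey HSD post-hocs, Cohen's d, and Benjamini-Hochberg FDR correction,
plus a battery runner that applies the right test per variable and corrects
the omnibus p-values as one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "GroupComparisonReport",
    "chi_square",
    "partial_pearson",
    "oneway_anova",
    "tukey_hsd",
    "cohens_d",
    "fdr_bh",
    "subtype_battery_report",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        if c.sum() < 1:
            raise ValueError("table total must be >= 1")
        self.counts = c.astype(float)


@dataclass
class GroupComparisonReport:
    table: pd.DataFrame
    posthoc: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)
    q: float = 0.05


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns ``(statistic, df, p)`` with ``df = (r-1)(c-1)``; requires every
    expected count to be positive and a genuinely two-way table.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    if np.any(expected <= 0):
        raise ValueError("zero expected count; collapse sparse categories first")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def partial_pearson(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing linear covariate effects.

    With no covariates this is the plain Pearson correlation; p comes from
    the t distribution with ``df = n - n_cov - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        Z = np.empty((x.size, 0))
    elif isinstance(covariates, pd.DataFrame):
        Z = covariates.drop(columns=["subject"], errors="ignore").to_numpy(dtype=float)
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
    n = x.size
    if n <= Z.shape[1] + 2:
        raise ValueError("need n > n_covariates + 2")
    D = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - Z.shape[1] - 2
    r_cl = min(max(r, -0.9999999999), 0.9999999999)
    t = r_cl * np.sqrt(df / (1.0 - r_cl**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    names = list(pd.unique(labels))
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    return groups, names


def oneway_anova(values, group_labels) -> tuple[float, float]:
    """Classical one-way ANOVA F test across the labeled groups."""
    groups, _ = _split_groups(values, group_labels)
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; F undefined")
    F, p = sps.f_oneway(*groups)
    return float(F), float(p)


def tukey_hsd(values, group_labels) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p)."""
    groups, names = _split_groups(values, group_labels)
    res = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                (
                    names[i],
                    names[j],
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                )
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with the unbiased pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def subtype_battery_report(
    scales: pd.DataFrame,
    subtype_labels,
    covariates: pd.DataFrame | None = None,
    q: float = 0.05,
    max_missing: float = 0.2,
    adjust_covariates: bool = False,
) -> GroupComparisonReport:
    """Run the right omnibus test per scale variable and FDR-correct the family.

    Numeric variables get a one-way ANOVA (plus Tukey post-hocs, themselves a
    BH family per variable); low-cardinality/categorical variables get a
    Pearson chi-square against subtype.  Variables with more than
    ``max_missing`` missingness are excluded and logged.  With
    ``adjust_covariates`` the ANOVA runs on covariate-residualized values.
    """
    labels = np.asarray(subtype_labels)
    rows = []
    posthoc = {}
    excluded = []
    Z = None
    if adjust_covariates and covariates is not None:
        Z = covariates.drop(columns=["subject"], errors="ignore").to_numpy(dtype=float)
    for col in scales.columns:
        if col == "subject":
            continue
        v = scales[col]
        missing = v.isna().mean()
        if missing > max_missing:
            excluded.append((col, f"{missing:.0%} missing"))
            continue
        ok = v.notna().to_numpy()
        vals = v[ok]
        labs = labels[ok]
        is_categorical = (not pd.api.types.is_numeric_dtype(vals)) or vals.nunique() <= 4
        try:
            if is_categorical:
                tab = pd.crosstab(vals, labs).to_numpy()
                stat, df, p = chi_square(tab)
                rows.append((col, "chi_square", stat, p))
            else:
                x = vals.to_numpy(dtype=float)
                if Z is not None:
                    D = np.column_stack([np.ones(ok.sum()), Z[ok]])
                    x = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
                F, p = oneway_anova(x, labs)
                rows.append((col, "anova", F, p))
                ph = tukey_hsd(x, labs)
                ph["q"] = fdr_bh(ph["p_adj"].to_numpy(), q)[0]
                posthoc[col] = ph
        except ValueError as err:
            excluded.append((col, str(err)))
    table = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
    if len(table):
        p_adj, sig = fdr_bh(table["p"].to_numpy(), q)
        table["p_fdr"] = p_adj
        table["significant"] = sig
    return GroupComparisonReport(table=table, posthoc=posthoc, excluded=excluded, q=q)
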