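"""Covariate-adjusted two-group comparisons with Bonferroni correction.

The default procedure mirrors a classical neuroimaging group analysis:
each per-subject metric is residualized against an intercept plus the named
covariates by pooled OLS (the group label is never part of the design), the
residuals are compared with an equal-variance two-sample t test, and the
family of tests is Bonferroni-corrected at alpha/n.  The reported t follows
the (group2 - group1) sign convention, groups sorted lexicographically.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panels import SubjectTable

__all__ = [
    "GroupComparisonResult",
    "residualize",
    "two_sample_t",
    "bonferroni",
    "chi_square_counts",
    "compare_groups",
]


@dataclasses.dataclass
class GroupComparisonResult:
    """Per-unit test results plus the family bookkeeping."""

    table: pd.DataFrame  # unit, t, df, p_raw, threshold, significant, means/sds
    family_size: int
    alpha: float
    threshold: float
    groups: tuple[str, str]
    covariates: list[str]

    @property
    def significant_units(self) -> list[str]:
        return self.table.loc[self.table["significant"], "unit"].tolist()


def residualize(
    values: np.ndarray,
    subjects: SubjectTable,
    covariates: list[str],
) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus named covariates.

    Fit on the pooled sample; the group label is never included.  With zero
    covariates this is mean-centering.  Raises on a rank-deficient design,
    naming the collinear columns.
    """
    y = np.asarray(values, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if y.shape[0] != len(subjects.frame):
        raise ValueError("values length must match subject table")
    x = np.column_stack([np.ones(y.shape[0]), subjects.covariates(covariates)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = ["(intercept)"] + list(covariates)
        # columns whose removal restores full rank are the collinear ones
        bad = [
            names[c]
            for c in range(1, x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, c, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def two_sample_t(
    adjusted: np.ndarray,
    group_mask: np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t test of group2 (mask True) minus group1 (mask False).

    Returns (t, df, two-sided p).  Equal-variance (pooled) by default;
    ``equal_var=False`` gives Welch's test.
    """
    y = np.asarray(adjusted, dtype=np.float64)
    mask = np.asarray(group_mask, dtype=bool)
    a, b = y[mask], y[~mask]  # group2, group1
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def bonferroni(alpha: float, n: int) -> float:
    """Per-test threshold alpha / n."""
    if n < 1:
        raise ValueError("family size must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n


def chi_square_counts(
    table: np.ndarray, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of a contingency table of counts.

    No continuity correction by default; set ``correction=True`` for Yates.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be a 2-D array of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def compare_groups(
    entropy: pd.DataFrame,
    subjects: SubjectTable,
    level: str = "network",
    k: int | None = None,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparisonResult:
    """Residualize, t-test per unit, Bonferroni over the family of units.

    ``entropy`` is the long-format table (subject_id, level, unit, k,
    entropy).  The family size n is the number of units tested at the
    requested level (and k, if given); results are sorted by raw p.
    """
    covariates = list(covariates or [])
    df = entropy[entropy["level"] == level]
    if k is not None:
        df = df[df["k"] == k]
    if df.empty:
        raise ValueError(f"no entropy rows at level={level!r}, k={k}")
    wide = df.pivot_table(
        index="subject_id", columns="unit", values="entropy", aggfunc="first"
    )
    ids = subjects.subject_ids
    missing = [s for s in ids if s not in wide.index]
    if missing:
        raise ValueError(f"subjects missing entropy values: {missing[:5]}")
    wide = wide.loc[ids]
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing entropy values for units: {bad[:5]}")

    mask = subjects.group_mask()
    g1, g2 = subjects.groups
    n_family = wide.shape[1]
    threshold = bonferroni(alpha, n_family)
    rows = []
    for unit in wide.columns:
        vals = wide[unit].to_numpy(dtype=np.float64)
        adj = residualize(vals, subjects, covariates)
        t, dof, p = two_sample_t(adj, mask, equal_var=equal_var)
        rows.append(
            {
                "unit": unit,
                "t": t,
                "df": dof,
                "p_raw": p,
                "threshold": threshold,
                "significant": bool(p < threshold),
                f"mean_{g1}": float(vals[~mask].mean()),
                f"sd_{g1}": float(vals[~mask].std(ddof=1)),
                f"mean_{g2}": float(vals[mask].mean()),
                f"sd_{g2}": float(vals[mask].std(ddof=1)),
                "direction": f"{g2}>{g1}" if t > 0 else f"{g1}>{g2}",
            }
        )
    table = (
        pd.DataFrame(rows).sort_values("p_raw", kind="mergesort").reset_index(drop=True)
    )
    return GroupComparisonResult(
        table=table,
        family_size=n_family,
        alpha=alpha,
        threshold=threshold,
        groups=(g1, g2),
        covariates=covariates,
    )
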