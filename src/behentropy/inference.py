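"""Group comparisons of dam-level measures.

The primary comparison is a t-test on the group-membership coefficient in an
ordinary least-squares model that allows for cohort effects:

    value ~ 1 + I(group == LBN) + C(cohort)

with the lexicographically first cohort as reference. Welch two-sample
t-tests and Pearson correlations (pooled or within-group/within-phase) cover
the remaining comparisons. Two-sided p-values throughout; no
multiple-testing correction is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    InsufficientDataError,
    ParameterError,
    RankDeficiencyError,
)

logger = logging.getLogger(__name__)

REFERENCE_GROUP = "CTL"


@dataclass
class GroupTestResult:
    """Cohort-adjusted group comparison via OLS.

    ``estimate`` is the group coefficient (mean shift of the non-reference
    group after removing additive cohort effects); ``t``/``p`` test it
    against zero with ``df`` residual degrees of freedom.
    """

    measure: str
    estimate: float
    se: float
    t: float
    df: int
    p: float
    n: int
    n_by_group: dict[str, int]
    params: dict[str, float]
    bse: dict[str, float]

    def summary(self) -> str:
        lines = [
            f"Cohort-adjusted group comparison: {self.measure}",
            f"  group effect  {self.estimate:+.4f}  (se {self.se:.4f})",
            f"  t({self.df}) = {self.t:.3f},  p = {self.p:.4g}",
            "  n = " + ", ".join(
                f"{g}: {n}" for g, n in sorted(self.n_by_group.items())
            ),
            "  coefficients:",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:<14s} {val:+.4f}  (se {self.bse[name]:.4f})")
        return "\n".join(lines)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    x: str
    y: str
    scope: str


class GroupComparison:
    """Model object for the cohort-adjusted group test.

    Build from per-dam scalars (or with :meth:`from_dataframe`); ``fit()``
    returns a :class:`GroupTestResult`.
    """

    def __init__(self, values, group, cohort, measure: str = "value"):
        values = np.asarray(values, dtype=float)
        group = np.asarray(group, dtype=object)
        cohort = np.asarray(cohort, dtype=object)
        if not (len(values) == len(group) == len(cohort)):
            raise ParameterError("values, group and cohort must align")
        keep = ~np.isnan(values)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "%s: excluding %d dams with missing values", measure, dropped
            )
        self.values = values[keep]
        self.group = group[keep]
        self.cohort = cohort[keep]
        self.measure = measure
        self.n_dropped = dropped

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str,
        group_col: str = "group",
        cohort_col: str = "cohort",
    ) -> "GroupComparison":
        if value_col not in df.columns:
            raise ParameterError(f"no column {value_col!r} in summary table")
        return cls(
            df[value_col], df[group_col], df[cohort_col], measure=value_col
        )

    def _design(self):
        groups = sorted(set(self.group))
        if len(groups) != 2:
            raise InsufficientDataError(
                f"need exactly 2 groups, got {groups}"
            )
        reference = (
            REFERENCE_GROUP if REFERENCE_GROUP in groups else groups[0]
        )
        treated = next(g for g in groups if g != reference)
        cohorts = sorted(set(self.cohort))
        names = ["intercept", f"group[{treated}]"]
        cols = [np.ones(len(self.values)), (self.group == treated).astype(float)]
        for c in cohorts[1:]:
            names.append(f"cohort[{c}]")
            cols.append((self.cohort == c).astype(float))
        X = np.column_stack(cols)
        return X, names, treated

    def fit(self) -> GroupTestResult:
        X, names, treated = self._design()
        n, p = X.shape
        if n <= p:
            raise InsufficientDataError(
                f"n = {n} observations cannot identify {p} coefficients"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # name the columns involved in the collinearity
            bad = [
                names[j]
                for j in range(p)
                if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
            ]
            raise RankDeficiencyError(
                "design matrix is rank deficient (e.g. a cohort containing "
                f"only one group); collinear columns: {bad}",
                columns=bad,
            )
        res = sm.OLS(self.values, X).fit()
        gi = names.index(f"group[{treated}]")
        counts = {g: int((self.group == g).sum()) for g in sorted(set(self.group))}
        return GroupTestResult(
            measure=self.measure,
            estimate=float(res.params[gi]),
            se=float(res.bse[gi]),
            t=float(res.tvalues[gi]),
            df=int(res.df_resid),
            p=float(res.pvalues[gi]),
            n=n,
            n_by_group=counts,
            params=dict(zip(names, map(float, res.params))),
            bse=dict(zip(names, map(float, res.bse))),
        )


def cohort_adjusted_group_test(
    values, group, cohort, measure: str = "value"
) -> GroupTestResult:
    """t-test on the group coefficient in an OLS model with cohort effects."""
    return GroupComparison(values, group, cohort, measure=measure).fit()


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite df; returns ``(t, df, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise InsufficientDataError(
                "both samples are constant and equal: t is undefined"
            )
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlations(
    summaries: pd.DataFrame,
    x: str,
    y: str,
    group: str | None = None,
    phase: str | None = None,
) -> CorrelationResult:
    """Pearson correlation of two dam-level measures over a scope.

    ``group``/``phase`` restrict the rows (within-group and/or within-phase
    scope); missing values are pairwise-deleted.
    """
    for col in (x, y):
        if col not in summaries.columns:
            raise ParameterError(f"no column {col!r} in summary table")
    df = summaries
    scope_parts = []
    if group is not None:
        df = df[df["group"] == group]
        scope_parts.append(f"group={group}")
    if phase is not None:
        df = df[df["phase"] == phase]
        scope_parts.append(f"phase={phase}")
    pairs = df[[x, y]].dropna()
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired observations, got {len(pairs)}"
        )
    r, p = stats.pearsonr(pairs[x], pairs[y])
    return CorrelationResult(
        r=float(r), n=len(pairs), p=float(p), x=x, y=y,
        scope=", ".join(scope_parts) or "pooled",
    )
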