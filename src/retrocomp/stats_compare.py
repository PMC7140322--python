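"""Statistical comparisons wired for the composition analyses.

Standard tests by design — one-way ANOVA / two-sample t-tests for group
comparisons (clade-within-host, host-within-clade, element-vs-host
exome), a Kolmogorov-Smirnov normality check, ordinary least-squares
regression for composition-vs-codon-statistic relationships, and a
paired z-test for observed-vs-expected RCDI.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps


@dataclasses.dataclass
class GroupComparison:
    """Result of one statistical test, one row of the comparisons table."""

    grouping: str
    test: str
    statistic: float
    dof: float
    p_value: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def compare_groups(
    values_by_group: dict[str, Sequence[float]],
    test: Literal["anova", "t_test"] = "anova",
    grouping: str = "",
) -> GroupComparison:
    """One-way ANOVA over >=2 groups, or a two-sample t-test for exactly 2."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    label = grouping or " vs ".join(values_by_group)
    if test == "t_test":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        res = _sps.ttest_ind(groups[0], groups[1])
        dof = len(groups[0]) + len(groups[1]) - 2
        return GroupComparison(label, "t_test", float(res.statistic), dof, float(res.pvalue))
    res = _sps.f_oneway(*groups)
    df_between = len(groups) - 1
    return GroupComparison(label, "anova", float(res.statistic), df_between, float(res.pvalue))


def normality_check(values: Sequence[float], grouping: str = "") -> GroupComparison:
    """Kolmogorov-Smirnov test of the sample against a fitted normal."""
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    if np.std(x) == 0:
        raise ValueError("constant vector: normality undefined")
    res = _sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return GroupComparison(grouping, "ks_normality", float(res.statistic), len(x), float(res.pvalue))


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def regress(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with r² and slope p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 3 or len(xa) != len(ya):
        raise ValueError("need n >= 3 paired observations")
    if np.std(xa) == 0:
        raise ValueError("zero-variance predictor")
    res = _sps.linregress(xa, ya)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(xa),
    )


def paired_z(observed: Sequence[float], expected: Sequence[float], grouping: str = "") -> GroupComparison:
    """Paired z-test on per-family (observed − expected) differences.

    Used for observed-vs-expected RCDI: z = mean(d) / (sd(d)/sqrt(n)),
    two-sided normal p-value.
    """
    d = np.asarray(observed, dtype=float) - np.asarray(expected, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    z = d.mean() / (sd / math.sqrt(len(d)))
    p = 2 * float(_sps.norm.sf(abs(z)))
    return GroupComparison(grouping, "paired_z", float(z), len(d) - 1, p)
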