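"""Group summaries and comparisons in the house style of the figures:
mean +/- SEM per genotype, one-way ANOVA with Tukey's multiple-comparison
test for three or more groups, Welch's unpaired t-test (Satterthwaite
degrees of freedom) for two, and star notation *p<0.05, **p<0.01,
***p<0.001 with strict inequalities — a p exactly on a threshold gets the
weaker annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupSummary", "PairwiseComparison", "GroupStats",
           "summarize_groups", "compare_groups", "star_notation"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    p_value: float
    stars: str


@dataclass
class GroupStats:
    """Per-group descriptive stats plus (optionally) pairwise tests."""

    groups: list[GroupSummary]
    comparisons: list[PairwiseComparison] = field(default_factory=list)
    test: str | None = None
    anova_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"group": g.label, "mean": g.mean,
                              "sem": g.sem, "n": g.n} for g in self.groups])

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"group_a": c.pair[0], "group_b": c.pair[1],
                              "p_value": c.p_value, "stars": c.stars,
                              "test": self.test} for c in self.comparisons])


def _sem(x: np.ndarray) -> float:
    # SEM = SD / sqrt(n), sample SD with ddof=1; undefined (nan) for n = 1
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def summarize_groups(samples: Mapping[str, Sequence[float]]) -> GroupStats:
    """Arithmetic mean, SEM and n per group (no tests)."""
    groups = []
    for label, values in samples.items():
        x = np.asarray(list(values), dtype=float)
        if x.size == 0:
            raise ValueError(f"group {label!r} is empty")
        groups.append(GroupSummary(str(label), float(x.mean()), _sem(x),
                                   int(x.size)))
    return GroupStats(groups)


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    method: str = "auto",
    alpha: float = 0.05,
) -> GroupStats:
    """Pairwise group comparison with the appropriate test.

    ``method`` is ``"welch_t"`` (exactly two groups), ``"anova_tukey"``
    (two or more; Tukey p-values are family-wise adjusted), or ``"auto"``
    which picks Welch for two groups and ANOVA+Tukey otherwise.
    """
    stats_out = summarize_groups(samples)
    labels = [g.label for g in stats_out.groups]
    arrays = {g.label: np.asarray(list(samples[g.label]), dtype=float)
              for g in stats_out.groups}
    small = [lab for lab, x in arrays.items() if x.size < 2]
    if small:
        raise ValueError(
            f"groups {small} have n < 2; comparison tests need n >= 2")
    if method == "auto":
        method = "welch_t" if len(labels) == 2 else "anova_tukey"

    means = {lab: float(x.mean()) for lab, x in arrays.items()}

    def _definite_p(p: float, mean_a: float, mean_b: float) -> float:
        # zero within-group variance makes the test statistic 0/0; the
        # data are then either literally identical (no evidence of a
        # difference) or separated with certainty
        if np.isnan(p):
            return 1.0 if np.isclose(mean_a, mean_b) else 0.0
        return float(p)

    if method == "welch_t":
        if len(labels) != 2:
            raise ValueError("welch_t requires exactly two groups")
        a, b = (arrays[lab] for lab in labels)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b, equal_var=False)
        p = _definite_p(float(res.pvalue), means[labels[0]], means[labels[1]])
        stats_out.comparisons = [
            PairwiseComparison((labels[0], labels[1]), p, star_notation(p))]
        stats_out.test = "welch_t"
    elif method == "anova_tukey":
        if len(labels) < 2:
            raise ValueError("anova_tukey requires at least two groups")
        with np.errstate(divide="ignore", invalid="ignore"):
            anova_p = float(
                stats.f_oneway(*[arrays[lab] for lab in labels]).pvalue)
            endog = np.concatenate([arrays[lab] for lab in labels])
            group_codes = np.concatenate(
                [[lab] * arrays[lab].size for lab in labels])
            tukey = pairwise_tukeyhsd(endog, group_codes, alpha=alpha)
        stats_out.anova_p = _definite_p(
            anova_p, min(means.values()), max(means.values()))
        uniq = [str(g) for g in tukey.groupsunique]
        comparisons = []
        # statsmodels orders p-values as combinations(groupsunique, 2)
        for (ga, gb), p in zip(combinations(uniq, 2), tukey.pvalues):
            p = _definite_p(float(p), means[ga], means[gb])
            comparisons.append(
                PairwiseComparison((ga, gb), p, star_notation(p)))
        stats_out.comparisons = comparisons
        stats_out.test = "anova_tukey"
    else:
        raise ValueError(f"unknown method {method!r}")
    return stats_out


def star_notation(p: float) -> str:
    """Significance stars: ***p<0.001, **p<0.01, *p<0.05, else 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
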