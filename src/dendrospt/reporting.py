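"""Summary statistics and nonparametric comparisons.

SPT quantities (D, dwell times, transition times) are heavily skewed, so
distributions are described as median ± interquartile range (IQR, the
25th–75th percentile interval) and compared with nonparametric tests:
two-tailed Mann-Whitney U for unpaired groups, Wilcoxon signed-rank for
paired ones, Kolmogorov-Smirnov for cumulative distributions. Quartiles use
linear interpolation between order statistics (the common "type 7" rule).
Raw two-tailed p-values are reported without multiple-comparison
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SummaryStats:
    """Median ± IQR summary of one numeric series."""

    median: float
    q25: float
    q75: float
    n: int
    unit: str = ""

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25

    def __str__(self) -> str:
        u = f" {self.unit}" if self.unit else ""
        return (
            f"median {self.median:.4g}{u} "
            f"(IQR {self.q25:.4g}–{self.q75:.4g}, n = {self.n})"
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group statistical comparison."""

    test: str  # mann_whitney | wilcoxon_paired | ks | t_test
    statistic: float
    p_value: float
    n1: int
    n2: int

    @property
    def stars(self) -> str:
        """Significance stars at the 0.05 / 0.01 / 0.001 levels."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def summarize(values, unit: str = "") -> SummaryStats:
    """Median and quartiles (linear interpolation) of a numeric series."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarize an empty series")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return SummaryStats(
        median=float(med), q25=float(q25), q75=float(q75), n=int(arr.size), unit=unit
    )


_TESTS = {"mann_whitney", "wilcoxon_paired", "ks", "t_test"}


def compare(
    group1,
    group2,
    test: str = "mann_whitney",
) -> ComparisonResult:
    """Two-tailed comparison of two groups with an established test.

    ``mann_whitney`` (unpaired, default), ``wilcoxon_paired`` (equal-length
    paired samples), ``ks`` (two-sample Kolmogorov-Smirnov on cumulative
    distributions) or ``t_test`` (unpaired Welch).
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if test == "wilcoxon_paired":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        if a.size < 3:
            raise ValueError("paired test requires n >= 3")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        if a.size < 3 or b.size < 3:
            raise ValueError("unpaired tests require n >= 3 per group")
        if test == "mann_whitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        elif test == "ks":
            res = stats.ks_2samp(a, b, alternative="two-sided")
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
    )


def histogram_table(values, bins: int = 20, range_=None):
    """Histogram counts plus empirical cumulative fractions.

    Returns a dict of arrays: bin edges, counts (summing to n) and the
    cumulative fraction at each bin's right edge (ending at 1.0).
    """
    arr = np.asarray(values, dtype=float)
    counts, edges = np.histogram(arr, bins=bins, range=range_)
    cum = np.cumsum(counts) / max(arr.size, 1)
    return {"edges": edges, "counts": counts, "cumulative": cum}
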