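"""Group-comparison statistics used throughout the pipeline.

The measured distributions (firing rates, correlations, entropies, model
KL divergences) are generally non-normal with unequal variances across
groups, so the workhorse comparison is the two-sided Brunner–Munzel rank
test (robust to both) with Bonferroni correction for multiple comparisons.
Normality (Kolmogorov–Smirnov) and variance homogeneity (Levene, absolute
deviations) checks document why the rank test is the right tool; the
Wilcoxon rank-sum test serves the paired word-vs-count entropy comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    corrected_alpha: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.corrected_alpha is None:
            return None
        return self.p_value < self.corrected_alpha


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 1) -> float:
    """Family-wise corrected per-test threshold alpha / n.

    ``n_comparisons`` is always explicit — e.g. 15 comparisons give the
    0.0033 threshold used for the density-group contrasts.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def brunner_munzel(sample_a: np.ndarray, sample_b: np.ndarray,
                   alternative: str = "two-sided",
                   corrected_alpha: float | None = None,
                   ) -> GroupComparisonResult:
    """Two-sided Brunner–Munzel test of stochastic equality.

    Rank-based relative-effect statistic with the t approximation and
    Satterthwaite degrees of freedom; valid under unequal variances and
    non-normality, and invariant under strictly monotone transforms of both
    samples. Degenerate input (every value tied across both samples) has no
    rank information: p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied across both samples: "
                      "Brunner–Munzel degenerate, p = 1")
        return GroupComparisonResult("brunner-munzel", 0.0, 1.0, a.size,
                                     b.size, corrected_alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = sps.brunnermunzel(a, b, alternative=alternative,
                                        distribution="t")
    if not np.isfinite(p):
        if max(a.min(), b.min()) > min(a.max(), b.max()):
            # complete separation: zero rank variance, t approximation breaks
            # down; fall back on the exact permutation bound
            from math import comb
            p = min(1.0, 2.0 / comb(a.size + b.size, a.size))
            stat = np.inf if np.median(b) > np.median(a) else -np.inf
            warnings.warn("samples completely separated: permutation-bound p")
        else:
            warnings.warn("degenerate rank variance: p = 1")
            stat, p = 0.0, 1.0
    return GroupComparisonResult("brunner-munzel", float(stat), float(p),
                                 a.size, b.size, corrected_alpha)


def wilcoxon_rank_sum(sample_a: np.ndarray, sample_b: np.ndarray,
                      alternative: str = "two-sided",
                      corrected_alpha: float | None = None,
                      ) -> GroupComparisonResult:
    """Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's ``method='auto'`` policy).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if np.array_equal(np.sort(a), np.sort(b)):
        return GroupComparisonResult("wilcoxon-rank-sum", a.size * b.size / 2,
                                     1.0, a.size, b.size, corrected_alpha)
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return GroupComparisonResult("wilcoxon-rank-sum", float(res.statistic),
                                 float(res.pvalue), a.size, b.size,
                                 corrected_alpha)


@dataclass
class DistributionChecks:
    normal: list[bool]          # per-group KS non-rejection at alpha
    ks_p: list[float]
    equal_variance: bool        # Levene non-rejection at alpha
    levene_p: float

    @property
    def rank_test_indicated(self) -> bool:
        """True when normality or variance homogeneity fails anywhere."""
        return (not all(self.normal)) or (not self.equal_variance)


def distribution_checks(samples: list[np.ndarray], alpha: float = 0.05,
                        ) -> DistributionChecks:
    """KS normality per group and Levene (absolute deviations) across groups.

    Each group is z-scored before the one-sample KS test against the standard
    normal (testing shape, not location/scale). Failure of either check
    motivates the Brunner–Munzel test over a t-test/ANOVA.
    """
    normal, ks_p = [], []
    for s in samples:
        s = np.asarray(s, dtype=float)
        if s.size < 5:
            raise ValueError("need at least 5 observations per group")
        z = (s - s.mean()) / (s.std(ddof=1) if s.std(ddof=1) > 0 else 1.0)
        p = sps.ks_1samp(z, sps.norm.cdf).pvalue
        ks_p.append(float(p))
        normal.append(bool(p >= alpha))
    lev = sps.levene(*samples, center="mean")  # absolute-deviation variant
    return DistributionChecks(normal=normal, ks_p=ks_p,
                              equal_variance=bool(lev.pvalue >= alpha),
                              levene_p=float(lev.pvalue))


def pairwise_group_tests(groups: dict[str, np.ndarray], alpha: float = 0.05,
                         n_comparisons: int | None = None,
                         test: str = "brunner-munzel") -> pd.DataFrame:
    """All pairwise group contrasts with Bonferroni correction, long format.

    ``n_comparisons`` defaults to the number of pairs actually tested; pass
    it explicitly to reproduce a fixed family size.
    """
    names = list(groups)
    pairs = list(combinations(names, 2))
    n_comp = n_comparisons if n_comparisons is not None else len(pairs)
    corr_alpha = bonferroni_alpha(alpha, n_comp)
    fn = brunner_munzel if test == "brunner-munzel" else wilcoxon_rank_sum
    rows = []
    for ga, gb in pairs:
        r = fn(groups[ga], groups[gb], corrected_alpha=corr_alpha)
        rows.append((ga, gb, r.test, r.statistic, r.p_value, corr_alpha,
                     r.significant))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "test",
                                       "statistic", "p", "corrected_alpha",
                                       "significant"])
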