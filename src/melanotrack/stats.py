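"""Group-comparison statistics.

Two tests cover every comparison the analyses need: the two-sided unpaired
rank-sum (Mann–Whitney / Wilcoxon rank-sum — the two names denote the same
unpaired test here) and the unpaired two-sided t test. For small samples
(combined n ≤ 20) the rank-sum p-value is computed by exact enumeration of
all group assignments, which handles ties via mid-ranks; larger samples use
the normal approximation with tie-corrected variance and continuity
correction. No multiple-testing correction is applied by default, matching
per-comparison reporting; Bonferroni/Benjamini–Hochberg adjusters are
provided for callers that want them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError

EXACT_MAX_COMBINED_N = 20


@dataclass
class GroupComparison:
    """Result of one two-group comparison."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    direction: str          # 'a>b', 'a<b' or 'a~b' by median (mean for t test)
    labels: Tuple[str, str] = ("A", "B")
    method: str = ""

    def summary(self) -> str:
        la, lb = self.labels
        return (
            f"{self.test} ({self.method}): {la} (n={self.n_a}) vs {lb} (n={self.n_b})\n"
            f"  statistic = {self.statistic:.6g}, two-sided p = {self.p_value:.4g}\n"
            f"  medians: {self.median_a:.6g} vs {self.median_b:.6g} ({self.direction})"
        )


def _rank_sum_statistic(x, y):
    ranks = sps.rankdata(np.concatenate([x, y]))
    return np.sum(ranks[: len(x)])


def _mann_whitney(a: np.ndarray, b: np.ndarray):
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # every assignment is tied: no evidence of a shift
        return n_a * n_b / 2.0, 1.0, "degenerate (all tied)"
    if n_a + n_b <= EXACT_MAX_COMBINED_N:
        res = sps.permutation_test(
            (a, b),
            _rank_sum_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        r_a = res.statistic
        u = r_a - n_a * (n_a + 1) / 2.0
        return float(u), float(res.pvalue), "exact enumeration (mid-ranks)"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "normal approximation, tie-corrected"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "mann_whitney",
    labels: Tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided comparison of two independent samples.

    ``test`` is ``"mann_whitney"`` (rank-sum; exact for combined n ≤ 20) or
    ``"t_test"`` (unpaired, equal-variance). Raises on empty samples; the t
    test needs at least 2 observations per group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both samples must be non-empty")
    if test == "mann_whitney":
        stat, p, method = _mann_whitney(a, b)
        da, db = np.median(a), np.median(b)
    elif test == "t_test":
        if len(a) < 2 or len(b) < 2:
            raise InvalidParameterError("t test needs n >= 2 per group")
        res = sps.ttest_ind(a, b, equal_var=True)
        stat, p, method = float(res.statistic), float(res.pvalue), "unpaired, equal variance"
        da, db = np.mean(a), np.mean(b)
    else:
        raise InvalidParameterError("test must be 'mann_whitney' or 't_test'")
    direction = "a>b" if da > db else ("a<b" if da < db else "a~b")
    return GroupComparison(
        test=test,
        statistic=stat,
        p_value=min(1.0, p),
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        direction=direction,
        labels=labels,
        method=method,
    )


def adjust_pvalues(p_values: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Optional multiple-testing adjustment ('bonferroni' or 'bh')."""
    p = np.asarray(p_values, dtype=float)
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise InvalidParameterError("method must be 'bonferroni' or 'bh'")
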