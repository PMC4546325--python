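"""Group-level summaries and comparisons of per-cell reversal frequencies.

Boxplot summaries use the 10/25/50/75/90 percentiles with linear
interpolation between order statistics.  Two-group comparisons follow an
n-conditional rule common in single-cell motility studies: the two-sided
Wilcoxon rank-sum (Mann-Whitney) test when either group has fewer than 40
cells, and the two-sample Student t-test (equal variances; Welch available
behind a flag) when both have 40 or more.  P-values are reported raw — no
multiple-testing correction is applied — and labeled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupStats",
    "TestResult",
    "summarize_group",
    "compare_groups",
    "dose_response",
    "speed_summary",
]

PERCENTILES = (10, 25, 50, 75, 90)

# both groups at or below this size: exact rank-sum null by full enumeration
_EXACT_WILCOXON_MAX_N = 8


@dataclass
class GroupStats:
    """Percentile summary of one group (strain or condition)."""

    label: str
    frequencies: np.ndarray
    n: int
    mean: float
    percentiles: dict[int, float] = field(default_factory=dict)

    @property
    def median(self) -> float:
        return self.percentiles[50]


@dataclass
class TestResult:
    test: str           # "wilcoxon" or "t_test"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    rule_reason: str
    flagged: bool = False


def summarize_group(frequencies, label: str = "") -> GroupStats:
    """Five-number percentile summary (10/25/50/75/90) with linear interpolation."""
    freq = np.asarray(frequencies, dtype=float)
    if freq.size == 0:
        raise ValueError("cannot summarize an empty group")
    pct = {p: float(np.percentile(freq, p)) for p in PERCENTILES}
    return GroupStats(
        label=label,
        frequencies=freq,
        n=int(freq.size),
        mean=float(freq.mean()),
        percentiles=pct,
    )


def select_test(n_a: int, n_b: int, threshold: int = 40) -> str:
    """Pure n-rule: Wilcoxon when either group is below the threshold."""
    return "wilcoxon" if min(n_a, n_b) < threshold else "t_test"


def compare_groups(
    a,
    b,
    n_threshold: int = 40,
    welch: bool = False,
) -> TestResult:
    """Two-sided comparison of two groups under the n-conditional rule.

    Wilcoxon rank-sum is used when ``min(n_a, n_b) < n_threshold`` (exact
    null by full enumeration when both groups have at most 8 untied
    values, normal approximation with tie correction otherwise); the
    two-sample Student t-test otherwise (``welch=True`` drops the
    equal-variance assumption).  Two groups with zero variance and equal
    means compare as p = 1 by convention, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    test = select_test(a.size, b.size, n_threshold)
    reason = (
        f"min(n)={min(a.size, b.size)} < {n_threshold} -> wilcoxon"
        if test == "wilcoxon"
        else f"min(n)={min(a.size, b.size)} >= {n_threshold} -> t_test"
    )
    degenerate = a.std() == 0 and b.std() == 0 and a.mean() == b.mean()
    if degenerate:
        return TestResult(test=test, statistic=0.0, p_value=1.0,
                          n_a=a.size, n_b=b.size,
                          rule_reason=reason + " (degenerate: zero variance, equal means)",
                          flagged=True)
    if test == "wilcoxon":
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        small = (max(a.size, b.size) <= _EXACT_WILCOXON_MAX_N
                 or a.size + b.size <= _EXACT_WILCOXON_MAX_N + 2)
        method = "exact" if small and not ties else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return TestResult(test="wilcoxon", statistic=float(res.statistic),
                          p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
                          rule_reason=reason + f" ({method})")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(test="t_test", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
                      rule_reason=reason + (" (welch)" if welch else " (student)"))


def dose_response(
    groups: dict | list[tuple[float, np.ndarray]],
    n_threshold: int = 40,
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Reversal frequency as a function of stimulant dose.

    ``groups`` maps dose (e.g. % IAA, v/v) to the per-cell frequencies
    measured at that dose.  Returns a table sorted by ascending dose with
    n, mean and percentiles per dose, plus the pairwise test between each
    pair of consecutive doses.  Duplicate dose labels are merged with a
    warning.
    """
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = list(groups)
    merged: dict[float, np.ndarray] = {}
    for dose, values in items:
        dose = float(dose)
        values = np.asarray(values, dtype=float)
        if dose in merged:
            warnings.warn(f"duplicate dose label {dose!r}: groups merged")
            merged[dose] = np.concatenate([merged[dose], values])
        else:
            merged[dose] = values
    if len(merged) < 2:
        raise ValueError("dose_response needs at least 2 distinct doses")
    doses = sorted(merged)
    rows = []
    for dose in doses:
        gs = summarize_group(merged[dose], label=f"{dose}")
        rows.append({
            "dose": dose,
            "n": gs.n,
            "mean_frequency_per_10min": gs.mean,
            **{f"p{p}": gs.percentiles[p] for p in PERCENTILES},
        })
    table = pd.DataFrame(rows)
    tests = [
        compare_groups(merged[d0], merged[d1], n_threshold=n_threshold)
        for d0, d1 in zip(doses[:-1], doses[1:])
    ]
    return table, tests


def speed_summary(tracks) -> dict:
    """Population speed: mean ± SD (µm/min) over per-cell mean speeds."""
    speeds = np.array([t.mean_speed for t in tracks], dtype=float)
    if speeds.size == 0:
        return {"mean_um_per_min": np.nan, "sd_um_per_min": np.nan, "n": 0}
    return {
        "mean_um_per_min": float(speeds.mean()),
        "sd_um_per_min": float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0,
        "n": int(speeds.size),
    }
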