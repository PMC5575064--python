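"""Two-group comparison of per-subject readouts.

Policy: values are summarized as mean ± SEM; differences between two groups
are tested two-sided at α = 0.05 with no multiple-testing correction.  The
source protocol names a "non-parametric t-Student Test", which is internally
contradictory, so nothing is silently guessed: the parametric t (Student and
Welch) and the Mann–Whitney U are all available, the default report carries
Welch alongside Mann–Whitney, and every result records the method used.
The Mann–Whitney null is exact (full enumeration) for groups of ≤ 8,
normal-approximated with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "compare_groups_all",
    "summarize_group",
    "ALPHA",
    "METHODS",
]

ALPHA = 0.05
METHODS = ("welch_t", "student_t", "mann_whitney")


@dataclass
class ComparisonResult:
    method_name: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def summarize_group(values) -> tuple[float, float]:
    """Mean and SEM (sample SD / √n).  SEM is 0 for n = 1 (a single subject
    carries no dispersion information; flagged by n, not by NaN)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    if not np.isfinite(v).all():
        raise ValueError("group values must be finite")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return mean, sem


def compare_groups(a, b, method: str = "welch_t", alpha: float = ALPHA) -> ComparisonResult:
    """Two-sided two-sample comparison.

    method ∈ {"welch_t", "student_t", "mann_whitney"}.  Both groups need
    n ≥ 2 finite values.  Degenerate case (zero variance in both groups,
    equal means) → statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {a.size} and {b.size})")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")

    mean_a, sem_a = summarize_group(a)
    mean_b, sem_b = summarize_group(b)

    degenerate = a.std() == 0.0 and b.std() == 0.0 and mean_a == mean_b
    if degenerate:
        stat, p = 0.0, 1.0
    elif method == "welch_t":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif method == "student_t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    else:
        exact = a.size <= 8 and b.size <= 8 and np.unique(np.r_[a, b]).size == a.size + b.size
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
        stat, p = res.statistic, res.pvalue
    if np.isnan(p):  # zero variance, equal means not caught above
        stat, p = 0.0, 1.0

    return ComparisonResult(
        method_name=method,
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        statistic=float(stat),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
        alpha=alpha,
    )


def compare_groups_all(a, b, alpha: float = ALPHA) -> dict[str, ComparisonResult]:
    """All three methods side by side (the default report)."""
    return {m: compare_groups(a, b, method=m, alpha=alpha) for m in METHODS}
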