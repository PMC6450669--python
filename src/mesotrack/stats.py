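"""Two-group comparison with a normality-gated test choice.

Groups are compared with either Welch's t-test (both samples consistent
with a Gaussian by Shapiro–Wilk at alpha = 0.05) or the two-sided
Mann–Whitney–Wilcoxon otherwise; mean ± SEM is always reported and the
chosen test is recorded.  An independent exact Mann–Whitney p-value by
full enumeration of rank assignments is provided as an oracle for small
tie-free samples.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
from scipy import stats as sps

from .model import ValidationError

__all__ = ["GroupComparison", "is_gaussian", "compare_groups", "exact_mww_p"]


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group comparison (two-sided)."""

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    test_used: str  # "mann_whitney" | "t_test"
    statistic: float
    p_value: float


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValidationError(f"sample {name!r}: need n >= 3 finite values")
    return arr


def is_gaussian(sample, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk gate: True iff normality is not rejected at ``alpha``.

    A zero-variance sample is reported as not Gaussian (the test is
    undefined for constant data).
    """
    arr = _as_sample(sample, "sample")
    if np.ptp(arr) == 0.0:
        return False
    return bool(sps.shapiro(arr).pvalue >= alpha)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U and p.

    Exact distribution for combined n <= 12 without ties; otherwise the
    normal approximation with tie and continuity correction.
    """
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    a, b, name_a: str = "a", name_b: str = "b", alpha: float = 0.05,
) -> GroupComparison:
    """Compare two samples with the gate-then-test procedure.

    Welch's unpaired two-sided t-test when both samples pass
    :func:`is_gaussian`; Mann–Whitney–Wilcoxon otherwise.
    """
    xa = _as_sample(a, name_a)
    xb = _as_sample(b, name_b)
    if is_gaussian(xa, alpha) and is_gaussian(xb, alpha):
        res = sps.ttest_ind(xa, xb, equal_var=False)
        test_used = "t_test"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        test_used = "mann_whitney"
        statistic, p = mann_whitney_p(xa, xb)
    return GroupComparison(
        name_a=name_a, name_b=name_b, n_a=xa.size, n_b=xb.size,
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        sem_a=_sem(xa), sem_b=_sem(xb),
        test_used=test_used, statistic=statistic, p_value=min(p, 1.0),
    )


def exact_mww_p(a, b) -> float:
    """Exact two-sided Mann–Whitney p by enumerating rank assignments.

    Restricted to small tie-free samples (combined n <= 12): every
    C(n_a+n_b, n_a) assignment of the pooled ranks to group A is
    enumerated and the two-sided p is the fraction whose U deviates
    from its null center at least as much as the observed U.
    """
    xa = np.asarray(a, dtype=float).reshape(-1)
    xb = np.asarray(b, dtype=float).reshape(-1)
    if xa.size == 0 or xb.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([xa, xb])
    if np.unique(pooled).size != pooled.size:
        raise ValidationError("exact enumeration requires tie-free samples")
    if pooled.size > 12:
        raise ValidationError("exact enumeration limited to combined n <= 12")
    na, nb = xa.size, xb.size
    u_obs = sum(1 for x in xa for y in xb if x > y)
    center = na * nb / 2.0
    dev = abs(u_obs - center)
    order = np.argsort(pooled)
    ranks = np.empty(pooled.size, dtype=int)
    ranks[order] = np.arange(pooled.size)
    count = 0
    total = 0
    all_ranks = set(range(pooled.size))
    for a_ranks in itertools.combinations(range(pooled.size), na):
        b_ranks = all_ranks - set(a_ranks)
        u = sum(1 for ra in a_ranks for rb in b_ranks if ra > rb)
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total
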