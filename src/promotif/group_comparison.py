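"""Distribution-level comparisons between a gene group and its background.

Motif counts are compared with a randomization (permutation) test: the group
is a subset of the background universe, so the null is built by drawing
random subsets of the same size from the background and recomputing the mean
difference.  GC content is compared with Welch's t test (unequal variances)
or one-way ANOVA for more than two groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed: float
    n_perm: int
    p_value: float
    seed: int
    group_size: int
    background_size: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def permutation_test(
    group_values: Sequence[float],
    background_values: Sequence[float],
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided randomization test on the difference of means.

    Observed statistic: mean(group) - mean(background).  Each of the
    ``n_perm`` null draws takes a uniform random subset of size |group| from
    the background (without replacement) and recomputes the statistic.  The
    Monte-Carlo p-value uses the add-one convention
    p = (1 + #{|T*| >= |T_obs|}) / (n_perm + 1), so p is never 0 and is
    bounded below by 1/(n_perm + 1).  Deterministic under a fixed seed.
    """
    group = np.asarray(group_values, dtype=float)
    background = np.asarray(background_values, dtype=float)
    if group.size == 0:
        raise ValueError("group must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if group.size > background.size:
        raise ValueError(
            f"group size {group.size} exceeds background size {background.size}"
        )
    bg_mean = background.mean()
    observed = float(group.mean() - bg_mean)
    rng = np.random.default_rng(seed)
    g = group.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = background[rng.choice(background.size, size=g, replace=False)].mean()
    null -= bg_mean
    b = int(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12))
    p = (1 + b) / (n_perm + 1)
    return PermutationResult(
        statistic_name="mean_difference",
        observed=observed,
        n_perm=n_perm,
        p_value=p,
        seed=seed,
        group_size=g,
        background_size=int(background.size),
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t test, two-sided.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; ANOVA undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
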