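"""Group statistics: log transform, pooled t-tests, correlation, power.

Connectivity and graph measures are right-skewed, so group comparisons
run on natural-log-transformed values with two-tailed pooled-variance
(Student) t-tests.  Effect size is partial eta squared,
``t^2 / (t^2 + df)``.  The a-priori power analysis inverts the
noncentral-t power curve of the two-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst


@dataclass
class StatResult:
    t: float
    df: int
    p: float
    eta_p2: float


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass
class PowerSpec:
    """Inputs for the a-priori sample-size computation."""

    effect_size_d: float = 0.8
    alpha: float = 0.05
    power: float = 0.80


def log_transform(values: np.ndarray) -> np.ndarray:
    """Natural log, elementwise; rejects non-positive values."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        bad = v[v <= 0][0]
        raise ValueError(f"log transform requires positive values (got {bad})")
    return np.log(v)


def independent_t(group_a: np.ndarray, group_b: np.ndarray) -> StatResult:
    """Two-tailed pooled-variance t-test with partial eta squared."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = sst.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    t = float(res.statistic)
    return StatResult(t=t, df=df, p=float(res.pvalue),
                      eta_p2=t * t / (t * t + df))


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with the two-tailed t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least three points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sst.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p))


def partial_eta_squared(t: float, df: int) -> float:
    """Effect size t^2 / (t^2 + df), e.g. for a published t statistic."""
    return t * t / (t * t + df)


def correlation_p_value(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via the t transform with n - 2 df."""
    if not -1 < r < 1:
        raise ValueError("r must lie strictly inside (-1, 1) for a p-value")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sst.t.sf(abs(t), n - 2))


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at per-group size n.

    Under the alternative the statistic follows a noncentral t with
    ``df = 2n - 2`` and noncentrality ``d * sqrt(n / 2)``.
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    tcrit = sst.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sst.nct.cdf(tcrit, df, nc) + sst.nct.cdf(-tcrit, df, nc))


def required_n(spec: PowerSpec = PowerSpec(), n_max: int = 100000) -> int:
    """Smallest per-group n reaching the target power.

    At the conventional large effect (d = 0.8) with alpha .05 and target
    power .80 this gives 26 participants per group.
    """
    if spec.effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < spec.alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < spec.power < 1:
        raise ValueError("target power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_two_sample_t(n, spec.effect_size_d, spec.alpha) >= spec.power:
            return n
    raise ValueError(f"required n exceeds {n_max}")
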