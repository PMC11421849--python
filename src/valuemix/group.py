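"""Cohort-level statistics: group split by integration style, t-tests on
GLM coefficients, and the integration-coefficient / distractor-effect
correlation.

Group inference follows the two-stage summary-statistics approach: each
participant contributes one fitted coefficient (or parameter), and the
cohort-level question is answered with ordinary one- or two-sample t-tests
and Pearson correlation on those per-participant values.  All p-values are
two-sided and uncorrected.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "split_by_mean_eta",
    "one_sample_t",
    "two_sample_t",
    "pearson_r",
    "near_zero_eta_filter",
]


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class CorrelationResult(NamedTuple):
    r: float
    df: int
    p: float


def split_by_mean_eta(etas: Sequence[float]) -> np.ndarray:
    """Split participants at the cohort-mean integration coefficient.

    Returns an array of labels: ``"multiplicative"`` for eta strictly above
    the mean, ``"additive"`` otherwise (ties at the mean go to additive —
    deterministic and documented).
    """
    etas = np.asarray(etas, dtype=float)
    if etas.size < 2:
        raise ValueError("need at least 2 participants to split")
    mean = etas.mean()
    return np.where(etas > mean, "multiplicative", "additive")


def one_sample_t(values: Sequence[float]) -> TTestResult:
    """Two-sided one-sample t-test of the mean against zero; df = N - 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.var(v, ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(v, 0.0)
    return TTestResult(float(res.statistic), v.size - 1, float(res.pvalue))


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t-test; df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    sa2 = np.var(a, ddof=1)
    sb2 = np.var(b, ddof=1)
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * sa2 + (b.size - 1) * sb2) / df
    if pooled == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation; p from t = r sqrt(df / (1 - r^2)), df = N - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), x.size - 2, float(res.pvalue))


def near_zero_eta_filter(etas: Sequence[float], threshold: float = 1e-6) -> np.ndarray:
    """Indices of participants whose eta is at or above the threshold.

    Used for the sensitivity re-test of the eta / distractor-effect
    correlation after removing effectively-additive participants.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    etas = np.asarray(etas, dtype=float)
    return np.flatnonzero(etas >= threshold)


def plot_parameter_distributions(etas, gammas, thetas, path=None):
    """Histograms of the fitted composite-model parameters (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    for ax, vals, name in zip(axes, (etas, gammas, thetas), ("eta", "gamma", "theta")):
        ax.hist(np.asarray(vals, dtype=float), bins=20, color="steelblue")
        ax.set_xlabel(name)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
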