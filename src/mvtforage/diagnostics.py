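"""Residual diagnostics and hypothesis tests for the fitted MVT model.

Covers the model-checking toolkit applied after the gain-curve fit: a
chi-square(2) Q-Q comparison of squared orthogonal residuals, an
observed-versus-predicted regression whose intercept indicates model bias,
paired two-tailed t-tests of observed against predicted values, and Welch
t-tests for group comparisons with possibly unequal variances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TTestResult",
    "BiasRegression",
    "DiagnosticsReport",
    "paired_t_test",
    "welch_t_test",
    "observed_vs_predicted_bias",
    "qq_chisq2",
    "histogram_bins",
    "build_gain_diagnostics",
]


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed t-test outcome.

    ``df`` is integer ``n - 1`` for the paired test and fractional
    (Welch–Satterthwaite) for the two-sample test. ``mean_diff`` is the mean
    of the paired differences, or ``mean(a) - mean(b)``; its sign matches
    the sign of ``t``. ``degenerate`` flags zero-variance inputs for which
    the statistic is infinite or undefined.
    """

    t: float
    df: float
    p: float
    mean_diff: float
    test_kind: str           # {"paired", "welch"}
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "mean_diff": self.mean_diff, "test_kind": self.test_kind,
            "degenerate": self.degenerate,
        }


def paired_t_test(observed, predicted) -> TTestResult:
    """Paired two-tailed t-test of per-record differences, df = n - 1."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    diffs = obs - pred
    md = float(diffs.mean())
    scale = max(float(np.abs(obs).max(initial=0.0)), float(np.abs(pred).max(initial=0.0)), 1.0)
    if diffs.std(ddof=1) <= 1e-12 * scale:
        if abs(md) <= 1e-12 * scale:
            return TTestResult(0.0, n - 1, 1.0, 0.0, "paired")
        return TTestResult(
            float(np.sign(md)) * np.inf, n - 1, 0.0, md, "paired", degenerate=True
        )
    res = stats.ttest_rel(obs, pred)
    return TTestResult(float(res.statistic), float(n - 1), float(res.pvalue), md, "paired")


def welch_t_test(group_a, group_b) -> TTestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    md = float(a.mean() - b.mean())
    degenerate = bool(
        (np.allclose(a.std(ddof=1), 0) and a.size == 2)
        or (np.allclose(b.std(ddof=1), 0) and b.size == 2)
    )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        float(res.statistic), float(res.df), float(res.pvalue), md, "welch",
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class BiasRegression:
    """OLS of observed on predicted: intercept 0 and slope 1 mean no bias."""

    intercept: float
    slope: float
    identity_line: tuple[tuple[float, float], tuple[float, float]]


def observed_vs_predicted_bias(observed, predicted) -> BiasRegression:
    """Regress observed values on predicted values (ordinary least squares).

    The predicted values sit on the x-axis, observed on the y-axis; the
    intercept indicates systematic over- or under-prediction, the slope
    proportional bias. Returns the identity-line endpoints for overlay.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 3:
        raise ValueError("bias regression needs n >= 3")
    if np.ptp(pred) == 0:
        raise ValueError("constant predictions: bias slope undefined")
    fit = sm.OLS(obs, sm.add_constant(pred)).fit()
    lo, hi = float(pred.min()), float(pred.max())
    return BiasRegression(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        identity_line=((lo, lo), (hi, hi)),
    )


def qq_chisq2(
    squared_residuals,
    rescale: bool = True,
    positions: str = "midpoint",
) -> tuple[np.ndarray, np.ndarray]:
    """Q-Q pairs of squared residuals against a chi-square(2) reference.

    Chi-square with 2 degrees of freedom is the exponential distribution
    with mean 2, so the theoretical quantile at probability ``p`` is exactly
    ``-2 * ln(1 - p)``. Plotting positions are ``(i - 0.5) / n``
    (``positions="midpoint"``) or Blom's ``(i - 3/8) / (n + 1/4)``.

    With ``rescale=True`` (default) the empirical values are divided by
    ``mean / 2`` so their mean matches the reference mean of 2 — squared
    orthogonal residuals carry arbitrary squared-data units, so only their
    shape is compared. Returns ``(theoretical, empirical)``, both sorted.
    """
    x = np.asarray(squared_residuals, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 squared residuals")
    if np.any(x < 0):
        raise ValueError("squared residuals must be non-negative")
    n = x.size
    i = np.arange(1, n + 1)
    if positions == "midpoint":
        p = (i - 0.5) / n
    elif positions == "blom":
        p = (i - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown plotting positions {positions!r}")
    theoretical = -2.0 * np.log1p(-p)
    empirical = np.sort(x)
    if rescale:
        m = empirical.mean()
        if m > 0:
            empirical = empirical / (m / 2.0)
    return theoretical, empirical


def histogram_bins(values) -> np.ndarray:
    """Freedman–Diaconis bin edges (falls back to sqrt rule for flat data)."""
    x = np.asarray(values, dtype=float)
    edges = np.histogram_bin_edges(x, bins="fd")
    if len(edges) < 3:
        edges = np.histogram_bin_edges(x, bins="sqrt")
    return edges


@dataclass
class DiagnosticsReport:
    """Bundle of model-fit diagnostics for one observed/predicted comparison."""

    bias: BiasRegression
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray
    hist_edges: np.ndarray
    paired_test: TTestResult
    welch_tests: dict[str, TTestResult] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bias": {"intercept": self.bias.intercept, "slope": self.bias.slope},
            "qq_theoretical": self.qq_theoretical.tolist(),
            "qq_empirical": self.qq_empirical.tolist(),
            "hist_edges": self.hist_edges.tolist(),
            "paired_test": self.paired_test.as_dict(),
            "welch_tests": {k: v.as_dict() for k, v in self.welch_tests.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def build_gain_diagnostics(observed, predicted, squared_residuals) -> DiagnosticsReport:
    """Assemble the standard post-fit diagnostics for the gain model.

    ``observed``/``predicted`` are the per-record gains (observed report vs
    model value), ``squared_residuals`` the squared orthogonal distances
    from the fit.
    """
    theo, emp = qq_chisq2(squared_residuals)
    return DiagnosticsReport(
        bias=observed_vs_predicted_bias(observed, predicted),
        qq_theoretical=theo,
        qq_empirical=emp,
        hist_edges=histogram_bins(np.asarray(squared_residuals, dtype=float)),
        paired_test=paired_t_test(observed, predicted),
    )
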