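"""Figure panels for the MVT analysis (scatter + fit, residuals, Q-Q, bias)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cluster import Dendrogram, ElbowResult
from .model import gain, predict_travel_time
from .odr import FitResult
from .travel import TravelEvaluation


def plot_gain_fit(fit: FitResult, T_obs, g_obs, path: str | Path) -> None:
    """Data with the ODR curve and an ordinary linear fit for comparison."""
    T_obs = np.asarray(T_obs, float)
    g_obs = np.asarray(g_obs, float)
    grid = np.linspace(0, max(T_obs.max() * 1.3, 1.0), 300)
    b, a = np.polyfit(T_obs, g_obs, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(T_obs, g_obs, s=18, alpha=0.7, label="records")
    ax.plot(grid, gain(fit.curve, grid), "C1", label="ODR gain curve")
    ax.plot(grid, a + b * grid, "C2--", lw=1, label="linear fit")
    ax.set_xlabel("patch residence time T (min)")
    ax.set_ylabel("gain (Euro)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diagnostic_panels(report, predicted, path: str | Path,
                           squared_residuals=None) -> None:
    """Residual scatter, Q-Q, histogram and observed-vs-predicted panels."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    theo, emp = report.qq_theoretical, report.qq_empirical
    pred = np.asarray(predicted, float)
    if squared_residuals is not None:
        sq = np.asarray(squared_residuals, float)
        axes[0, 0].scatter(pred, np.sqrt(sq), s=14, alpha=0.7)
        axes[0, 0].set_xlabel("predicted")
        axes[0, 0].set_ylabel("||D||")
        axes[1, 0].hist(sq, bins=report.hist_edges)
        axes[1, 0].set_xlabel("squared residual")
    axes[0, 1].scatter(theo, emp, s=14, alpha=0.7)
    lim = max(theo.max(), emp.max())
    axes[0, 1].plot([0, lim], [0, lim], "k--", lw=1)
    axes[0, 1].set_xlabel("chi-square(2) quantiles")
    axes[0, 1].set_ylabel("scaled squared residuals")
    obs_line = report.bias.intercept + report.bias.slope * pred
    order = np.argsort(pred)
    axes[1, 1].plot(pred[order], obs_line[order], "C1", label="bias regression")
    (x0, y0), (x1, y1) = report.bias.identity_line
    axes[1, 1].plot([x0, x1], [y0, y1], "k--", lw=1, label="identity")
    axes[1, 1].set_xlabel("predicted")
    axes[1, 1].set_ylabel("observed")
    axes[1, 1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_travel_panels(ev: TravelEvaluation, fit: FitResult, T_obs,
                       path: str | Path) -> None:
    """Observed/predicted travel times against residence time, plus residuals."""
    T_obs = np.asarray(T_obs, float)
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.6))
    grid = np.linspace(0.5, max(T_obs.max() * 1.3, 1.0), 300)
    axes[0].scatter(T_obs, ev.t_obs, s=14, alpha=0.7, label="observed")
    axes[0].plot(grid, predict_travel_time(fit.curve, grid), "C1",
                 label="tangent prediction")
    axes[0].set_xlabel("patch residence time T (min)")
    axes[0].set_ylabel("travel time t (min, signed)")
    axes[0].legend(frameon=False, fontsize=8)
    axes[1].scatter(ev.t_pred, ev.residuals, s=14, alpha=0.7)
    axes[1].axhline(0, color="k", lw=1)
    axes[1].set_xlabel("predicted travel time")
    axes[1].set_ylabel("residual")
    axes[2].scatter(ev.t_pred, ev.t_obs, s=14, alpha=0.7)
    lo = min(ev.t_pred.min(), ev.t_obs.min())
    hi = max(ev.t_pred.max(), ev.t_obs.max())
    axes[2].plot([lo, hi], [lo, hi], "k--", lw=1)
    axes[2].set_xlabel("predicted")
    axes[2].set_ylabel("observed")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scree(elbow: ElbowResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ks = np.arange(1, len(elbow.series) + 1)
    ax.plot(ks, elbow.series, "o-")
    ax.axvline(elbow.k, color="C1", ls="--", lw=1, label=f"elbow k={elbow.k}")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("merge height")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(dendro: Dendrogram, path: str | Path) -> None:
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(7, 4))
    scipy_dendrogram(dendro.merges, no_labels=dendro.n_leaves > 40, ax=ax,
                     color_threshold=0.0)
    ax.set_ylabel("merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
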