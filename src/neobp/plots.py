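"""Agreement figures: Bland-Altman and predicted-vs-true scatter plots
with the accuracy guideline lines clinicians expect on device-validation
reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .agreement import FDA_MAE_LIMIT, regression_fits  # noqa: E402

__all__ = ["bland_altman_plot", "pred_vs_truth_plot"]

_COMPONENT_TITLES = {"sbp": "Systolic BP", "dbp": "Diastolic BP",
                     "map": "Mean arterial BP"}


def bland_altman_plot(pred: np.ndarray, truth: np.ndarray, path: str | Path,
                      title: str = "") -> None:
    """Per-component difference-vs-average scatter with +-2 SD limits of
    agreement (red dotted) and +-5 mmHg accuracy guidelines (green)."""
    pred = np.atleast_2d(pred)
    truth = np.atleast_2d(truth)
    fig, axes = plt.subplots(1, pred.shape[1], figsize=(4 * pred.shape[1], 3.2),
                             squeeze=False)
    for j, name in enumerate(("sbp", "dbp", "map")[: pred.shape[1]]):
        ax = axes[0, j]
        d = pred[:, j] - truth[:, j]
        avg = 0.5 * (pred[:, j] + truth[:, j])
        ax.scatter(avg, d, s=6, alpha=0.4)
        mu, sd = np.mean(d), np.std(d, ddof=1)
        ax.axhline(mu, color="k", lw=1)
        for y in (mu - 2 * sd, mu + 2 * sd):
            ax.axhline(y, color="r", ls=":", lw=1)
        for y in (-FDA_MAE_LIMIT, FDA_MAE_LIMIT):
            ax.axhline(y, color="g", ls="--", lw=1)
        ax.set_title(_COMPONENT_TITLES[name])
        ax.set_xlabel("average (mmHg)")
        ax.set_ylabel("difference (mmHg)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pred_vs_truth_plot(pred: np.ndarray, truth: np.ndarray, path: str | Path,
                       title: str = "") -> None:
    """Predicted vs true scatter with the unconstrained (blue),
    zero-intercept (green) and identity (grey) fits."""
    pred = np.atleast_2d(pred)
    truth = np.atleast_2d(truth)
    fig, axes = plt.subplots(1, pred.shape[1], figsize=(4 * pred.shape[1], 3.4),
                             squeeze=False)
    for j, name in enumerate(("sbp", "dbp", "map")[: pred.shape[1]]):
        ax = axes[0, j]
        x, y = truth[:, j], pred[:, j]
        fits = regression_fits(y, x)
        ax.scatter(x, y, s=6, alpha=0.4)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, fits.slope * grid + fits.intercept, "b-",
                label=f"fit (rms {fits.rms:.1f})")
        ax.plot(grid, fits.zero_intercept_slope * grid, "g-",
                label=f"0-intercept (rms {fits.zero_intercept_rms:.1f})")
        ax.plot(grid, grid, color="grey",
                label=f"identity (rms {fits.identity_rms:.1f})")
        ax.set_title(_COMPONENT_TITLES[name])
        ax.set_xlabel("reference (mmHg)")
        ax.set_ylabel("predicted (mmHg)")
        ax.legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
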