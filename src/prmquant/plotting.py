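"""Diagnostic plots: calibration curves, residuals, breakpoints."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .calibration import CalibrationCurve, QuantEstimate, SegmentedFit

__all__ = ["plot_calibration", "plot_breakpoint", "plot_residuals"]


def plot_calibration(
    curve: CalibrationCurve, estimate: QuantEstimate | None, path
) -> None:
    """Ratio vs concentration with the fitted line, exclusions and the
    ratio = 1 quantification point."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [p.heavy_concentration for p in curve.points]
    ys = [p.ratio for p in curve.points]
    ax.plot(xs, ys, "o", label="retained", color="tab:blue")
    for p, reason in curve.excluded:
        ax.plot(
            p.heavy_concentration, p.ratio, "x", color="tab:red",
            label=None,
        )
    grid = np.linspace(min(xs), max(xs), 50)
    ax.plot(grid, curve.intercept + curve.slope * grid, "k-", lw=1)
    ax.axhline(1.0, ls=":", color="grey")
    if estimate is not None:
        ax.axvline(estimate.concentration, ls=":", color="grey")
        ax.set_title(
            f"{curve.stage} curve: "
            f"{estimate.concentration:.3g} µg/mL (±{estimate.standard_error:.2g})"
        )
    ax.set_xlabel("spiked heavy concentration (µg/mL)")
    ax.set_ylabel("heavy/light area ratio")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_breakpoint(points, seg: SegmentedFit, path) -> None:
    """Heavy peak area vs concentration on log-log axes with the two fitted
    segments and the breakpoint ψ as a vertical dashed line."""
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, "o", ms=4)
    left = np.linspace(x.min(), seg.psi, 25)
    right = np.linspace(seg.psi, x.max(), 25)

    def line(seg_b0, seg_b1, grid):
        if seg.transform == "log":
            return 10.0 ** (seg_b0 + seg_b1 * np.log10(grid))
        return seg_b0 + seg_b1 * grid

    ax.plot(left, line(seg.left_intercept, seg.left_slope, left), "-",
            color="tab:orange")
    ax.plot(right, line(seg.right_intercept, seg.right_slope, right), "-",
            color="tab:green")
    ax.axvline(seg.psi, ls="--", color="k")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("spiked heavy concentration (µg/mL)")
    ax.set_ylabel("heavy peak area")
    ax.set_title(f"breakpoint ψ = {seg.psi:.3g} µg/mL")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_residuals(curve: CalibrationCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    xs = np.array([p.heavy_concentration for p in curve.points])
    ys = np.array([p.ratio for p in curve.points])
    resid = ys - (curve.intercept + curve.slope * xs)
    ax.plot(xs, resid, "o", ms=4)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("spiked heavy concentration (µg/mL)")
    ax.set_ylabel("residual ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
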