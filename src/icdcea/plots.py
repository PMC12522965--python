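"""Matplotlib figures: CE plane, acceptability curve, tornado diagram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import CEACCurve, PSASample, TornadoEntry, TwoWayGrid

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado", "plot_two_way"]


def plot_ce_plane(sample: PSASample, wtp: float, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(sample.delta_effect, sample.delta_cost, s=8, alpha=0.5,
               label="PSA iterations")
    xs = np.array(ax.get_xlim())
    ax.plot(xs, wtp * xs, "r--", label=f"WTP = {wtp:,.0f} $/QALY")
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(curve: CEACCurve, wtp: float, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp_grid, curve.prob_ce, label="ICD vs. pharmaceutical")
    ax.axvline(wtp, color="r", ls="--", lw=0.8, label=f"WTP = {wtp:,.0f}")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness-to-pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tornado(
    entries: list[TornadoEntry], base_icer: float, path: str | Path, top: int = 12
) -> Path:
    shown = [e for e in entries if np.isfinite(e.range_width)][:top]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(shown), 4) + 1.5))
    ypos = np.arange(len(shown))[::-1]
    for y, e in zip(ypos, shown):
        lo = min(e.low_icer, e.high_icer)
        hi = max(e.low_icer, e.high_icer)
        ax.barh(y, hi - lo, left=lo, height=0.6, color="steelblue")
    ax.axvline(base_icer, color="k", lw=1.0, label=f"base ICER = {base_icer:,.0f}")
    ax.set_yticks(ypos)
    ax.set_yticklabels([e.parameter_id for e in shown], fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    ax.set_title("Tornado diagram")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_two_way(grid: TwoWayGrid, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(
        grid.b_values,
        grid.a_values,
        grid.icd_preferred.astype(float),
        cmap="RdYlGn",
        vmin=0.0,
        vmax=1.0,
        shading="nearest",
    )
    ax.set_xlabel(grid.parameter_b)
    ax.set_ylabel(grid.parameter_a)
    ax.set_title(f"Preferred strategy at WTP {grid.wtp:,.0f} (green = ICD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
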