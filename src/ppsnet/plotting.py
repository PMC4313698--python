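"""Figure helpers mirroring the model's standard panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .boundary import BoundaryFit
from .experiments import RFMapResult, RTCurve
from .model import Network, SimulationResult


def plot_activity_maps(net: Network, result: SimulationResult,
                       path: str | Path) -> None:
    """Steady-state activity of both maps plus the multisensory unit."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3),
                             gridspec_kw={"width_ratios": [2, 4, 1]})
    im0 = axes[0].imshow(result.final_tactile.T, origin="lower",
                         extent=(0, net.tactile.grid.extent_x,
                                 0, net.tactile.grid.extent_y),
                         vmin=0, vmax=1, aspect="equal", cmap="viridis")
    axes[0].set_title("tactile map")
    im1 = axes[1].imshow(result.final_auditory.T, origin="lower",
                         extent=(0, net.auditory.grid.extent_x,
                                 0, net.auditory.grid.extent_y),
                         vmin=0, vmax=1, aspect="equal", cmap="viridis")
    axes[1].axvline(net.hand.x_interval[1], color="w", ls="--", lw=1)
    axes[1].set_title("auditory map")
    axes[2].bar([0], [result.final_ms], color="gray")
    axes[2].set_ylim(0, 1.05)
    axes[2].set_xticks([])
    axes[2].set_title("multisensory")
    fig.colorbar(im1, ax=axes[:2].tolist(), shrink=0.8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_rf_maps(maps: dict[str, RFMapResult], path: str | Path) -> None:
    """Mean multisensory activation vs sound distance, one bar set per net."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    n = len(maps)
    for i, (label, m) in enumerate(maps.items()):
        width = 8.0 / max(n, 1)
        ax.bar(m.distances + (i - (n - 1) / 2) * width, m.mean, width=width,
               yerr=m.sem, label=label, capsize=2)
    ax.set_xlabel("sound distance from hand (cm)")
    ax.set_ylabel("multisensory activation")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_rt_curves(curves: dict[str, tuple[RTCurve, BoundaryFit | None]],
                   path: str | Path) -> None:
    """Mean network RT vs sound distance with fitted sigmoids and xc lines."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for label, (curve, fit) in curves.items():
        line = ax.errorbar(curve.distances, curve.mean, yerr=curve.sem,
                           fmt="o", ms=4, label=label)
        if fit is not None and fit.converged:
            xs = np.linspace(curve.distances.min(), curve.distances.max(), 200)
            ax.plot(xs, fit.predict(xs), color=line[0].get_color(), lw=1)
            ax.axvline(fit.xc, color=line[0].get_color(), ls="--", lw=1)
    ax.set_xlabel("sound distance from hand (cm)")
    ax.set_ylabel("network tactile RT (ms)")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_behavioral_fit(fits: dict[str, BoundaryFit], points: dict[str, tuple],
                        path: str | Path) -> None:
    """Behavioral RT vs touch-delivery time with per-session sigmoids."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for label, (x, y) in points.items():
        sc = ax.plot(x, y, "o", ms=4, label=label)
        fit = fits.get(label)
        if fit is not None and fit.converged:
            xs = np.linspace(min(x), max(x), 200)
            ax.plot(xs, fit.predict(xs), color=sc[0].get_color(), lw=1)
            ax.axvline(fit.xc, color=sc[0].get_color(), ls="--", lw=1)
    ax.set_xlabel("touch delivery time (ms)")
    ax.set_ylabel("tactile RT (ms)")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
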