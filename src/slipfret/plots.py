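"""Figure helpers: TDP heat maps, dwell histograms, burst 2-D plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bursts import static_fret_line
from .kinetics import CumulativeDwells, TdpHistogram
from .mixture import MixtureFit

__all__ = [
    "plot_trace",
    "plot_tdp",
    "plot_cumulative_dwells",
    "plot_fret_histogram",
    "plot_e_vs_tau",
]


def plot_trace(trace, idealized=None, max_seconds=20.0):
    """Donor/acceptor intensities and apparent FRET for one trace."""
    n = min(trace.n_frames, int(max_seconds / trace.bin_width))
    t = trace.times[:n]
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 4))
    ax1.plot(t, trace.donor[:n], color="green", lw=0.7, label="donor")
    ax1.plot(t, trace.acceptor[:n], color="red", lw=0.7, label="acceptor")
    ax1.set_ylabel("counts/frame")
    ax1.legend(frameon=False, fontsize=8)
    ax2.plot(t, trace.e_apparent[:n], color="0.4", lw=0.7)
    if idealized is not None:
        ax2.plot(t, idealized.e_idealized[:n], color="red", lw=1.2)
    ax2.set_ylim(-0.05, 1.05)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel(r"$E_\mathrm{app}$")
    fig.tight_layout()
    return fig


def plot_tdp(tdp: TdpHistogram):
    """Transition density heat map over (E before, E after)."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ex = tdp.edges
    im = ax.pcolormesh(ex, ex, tdp.counts.T, cmap="viridis")
    ax.plot([0, 1], [0, 1], color="w", lw=0.5, ls="--")
    ax.set_xlabel("E before")
    ax.set_ylabel("E after")
    ax.set_title(f"TDP (symmetry {tdp.symmetry_score:.2f}, n={tdp.n_transitions})", fontsize=9)
    fig.colorbar(im, ax=ax, label="transitions")
    fig.tight_layout()
    return fig


def plot_cumulative_dwells(cum: CumulativeDwells):
    """Pooled dwell-time histogram with its single-exponential fit."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    centers = 0.5 * (cum.edges[:-1] + cum.edges[1:])
    width = cum.edges[1] - cum.edges[0]
    ax.bar(centers, cum.counts, width=width, color="0.7", edgecolor="none")
    if cum.exp_fit.ok:
        k = cum.exp_fit.rate
        t = np.linspace(cum.edges[0], cum.edges[-1], 200)
        scale = cum.dwells.size * width * k
        ax.plot(t, scale * np.exp(-k * t), "r-", lw=1.2, label=f"k = {k:.2f} s$^{{-1}}$")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("count")
    fig.tight_layout()
    return fig


def plot_fret_histogram(e_values, fit: MixtureFit | None = None, bins=50, e_range=(-0.1, 1.1)):
    """Burst-E histogram with an optional mixture-fit overlay."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    counts, edges, _ = ax.hist(e_values, bins=bins, range=e_range, color="0.7")
    if fit is not None:
        x = np.linspace(*e_range, 400)
        bw = edges[1] - edges[0]
        total = np.zeros_like(x)
        for w, mu, sg in zip(fit.weights, fit.means, fit.sigmas):
            comp = w * np.exp(-0.5 * ((x - mu) / sg) ** 2) / (sg * np.sqrt(2 * np.pi))
            comp *= len(np.asarray(e_values)) * bw
            total += comp
            ax.plot(x, comp, lw=0.8)
        ax.plot(x, total, "k-", lw=1.2)
    ax.set_xlabel(r"$E_\mathrm{burst}$")
    ax.set_ylabel("bursts")
    fig.tight_layout()
    return fig


def plot_e_vs_tau(e_values, tau_values, tau_D0: float, bins=60):
    """2-D histogram of burst E vs donor lifetime with the static FRET line."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.hist2d(tau_values, e_values, bins=bins, range=[[0, tau_D0 * 1.2], [-0.1, 1.1]], cmap="Blues")
    tau = np.linspace(0, tau_D0, 100)
    ax.plot(tau, static_fret_line(tau, tau_D0), "r-", lw=1.0, label="static FRET line")
    ax.set_xlabel(r"$\tau_{D(A)}$ (ns)")
    ax.set_ylabel(r"$E_\mathrm{burst}$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
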