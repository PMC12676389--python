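"""Publication-style figures: histogram + two-Gaussian overlay, example
traces with idealization, and cluster-size cumulative-probability curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import ClusterStats, CorrectedTrace, EnsembleHistogram, FretTrace, GaussianMixtureFit


def _gauss(x, a, mu, s):
    return a * np.exp(-0.5 * ((x - mu) / s) ** 2) / (s * np.sqrt(2 * np.pi))


def plot_histogram_fit(
    hist: EnsembleHistogram, fit: GaussianMixtureFit, path: str | Path
) -> None:
    centers = hist.bin_centers
    width = float(hist.bin_edges[1] - hist.bin_edges[0])
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.bar(centers, hist.ensemble_mean, width=width * 0.95, yerr=hist.ensemble_sem,
           color="0.8", edgecolor="0.4", linewidth=0.5, error_kw={"lw": 0.7})
    xs = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
    low = width * _gauss(xs, fit.areas[0], fit.means[0], fit.sigmas[0])
    high = width * _gauss(xs, fit.areas[1], fit.means[1], fit.sigmas[1])
    ax.plot(xs, low, color="tab:blue", lw=1.2,
            label=f"low-E {100 * fit.fractions[0]:.1f}%")
    ax.plot(xs, high, color="tab:red", lw=1.2,
            label=f"high-E {100 * fit.fractions[1]:.1f}%")
    ax.plot(xs, low + high, color="k", lw=1.4)
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("probability per bin")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trace(
    trace: CorrectedTrace, ft: FretTrace | None, path: str | Path
) -> None:
    t = np.arange(trace.n_frames) * trace.frame_period
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 3.6), sharex=True)
    ax1.plot(t, trace.donor, color="tab:green", lw=0.6, label="donor")
    ax1.plot(t, trace.acceptor, color="tab:red", lw=0.6, label="acceptor")
    if trace.acceptor_bleach_frame is not None:
        ax1.axvline(trace.acceptor_bleach_frame * trace.frame_period,
                    color="0.5", ls="--", lw=0.8)
    ax1.set_ylabel("intensity (a.u.)")
    ax1.legend(frameon=False, fontsize=8, ncol=2)
    if ft is not None:
        te = np.arange(ft.efficiency.size) * trace.frame_period
        ax2.plot(te, ft.efficiency, color="k", lw=0.6)
        if ft.idealized_state is not None:
            means = [np.mean(ft.efficiency[ft.idealized_state == s])
                     for s in np.unique(ft.idealized_state)]
            ideal = np.asarray(means)[ft.idealized_state]
            ax2.plot(te, ideal, color="tab:red", lw=1.2)
    ax2.set_ylim(-0.25, 1.25)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("FRET E")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_cdfs(stats: dict[str, ClusterStats], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    inset = fig.add_axes([0.58, 0.25, 0.3, 0.3])
    for cond, s in sorted(stats.items()):
        sizes, cdf = s.cumulative_probability()
        ax.step(sizes, cdf, where="post", label=cond)
        freq = s.frequency_distribution
        inset.bar(list(freq.keys()), list(freq.values()), alpha=0.5, label=cond)
    ax.set_xlabel("cluster size (particles)")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False, fontsize=8, loc="lower right")
    inset.set_xlabel("size", fontsize=7)
    inset.set_ylabel("count", fontsize=7)
    inset.tick_params(labelsize=6)
    fig.savefig(path, dpi=150)
    plt.close(fig)
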