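"""Figure helpers: pixel-intensity scatter, morphometry bars, recovery curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_intensity_scatter", "plot_morphometry_bars",
           "plot_recovery_curves", "plot_fss_vs_css"]


def plot_intensity_scatter(dapi, gfp, mask, path, r_p=None):
    """Red (DAPI) vs green (GFP) per-pixel intensity scatter for a nucleus."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(np.asarray(dapi)[mask], np.asarray(gfp)[mask],
               s=2, alpha=0.3, color="seagreen")
    ax.set_xlabel("DAPI intensity")
    ax.set_ylabel("GFP intensity")
    if r_p is not None:
        ax.set_title(f"$r_p$ = {r_p:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_morphometry_bars(summary, path):
    """Mean CN and CS per construct with SEM bars."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    x = np.arange(len(summary))
    axes[0].bar(x, summary["mean_CN"], yerr=summary["sem_CN"], capsize=3)
    axes[0].set_ylabel("chromocenter number (CN)")
    axes[1].bar(x, summary["mean_CS_px2"], yerr=summary["sem_CS_px2"], capsize=3)
    axes[1].set_ylabel("chromocenter size (CS, px$^2$)")
    for ax in axes:
        ax.set_xticks(x)
        ax.set_xticklabels(summary["construct"], rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_recovery_curves(normalized_by_construct, path):
    """Mean full-scale recovery curve per construct, normalized to 1."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, traces in normalized_by_construct.items():
        tau = traces[0].tau_s
        mean = np.mean([t.post for t in traces], axis=0)
        ax.plot(tau, mean, label=name, lw=1)
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("normalized recovery")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fss_vs_css(records, path):
    fig, ax = plt.subplots(figsize=(4, 3.5))
    xs = [r.css for r in records if r.fss is not None and r.css is not None]
    ys = [r.fss for r in records if r.fss is not None and r.css is not None]
    ax.scatter(xs, ys, color="firebrick")
    for r in records:
        if r.fss is not None and r.css is not None:
            ax.annotate(r.mutation, (r.css, r.fss), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("clinical severity score (CSS)")
    ax.set_ylabel("functional severity score (FSS)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
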