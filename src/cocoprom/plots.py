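"""Optional plotting helpers (require matplotlib, `pip install cocoprom[plot]`)."""

from __future__ import annotations

import numpy as np

from .stats import linear_fit


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def scatter_with_fit(x, y, path, xlabel="TSS2 log2FC", ylabel="TSS3 log2FC"):
    """Scatter of paired log2FCs with the OLS line and its 95% band."""
    plt = _plt()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = linear_fit(x, y)
    grid = np.linspace(x.min(), x.max(), 200)
    mean, lo, hi = fit.band(grid)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=6, alpha=0.4, color="#444444", linewidths=0)
    ax.plot(grid, mean, color="crimson")
    ax.fill_between(grid, lo, hi, color="crimson", alpha=0.2, linewidth=0)
    ax.axhline(0, lw=0.5, color="0.6")
    ax.axvline(0, lw=0.5, color="0.6")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def metaprofile_curve(profile, path, label="signal", n_flank_bins=0):
    """Line plot of a per-bin metaprofile."""
    plt = _plt()
    profile = np.asarray(profile, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(np.arange(profile.size), profile, color="#2a6fb0")
    ax.set_xlabel("scaled position (bins)")
    ax.set_ylabel(f"mean {label}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def violin_by_group(groups: dict, path, ylabel="value"):
    """Violin summaries, one per named group."""
    plt = _plt()
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 1.5, 3))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(names) + 1), names)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
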