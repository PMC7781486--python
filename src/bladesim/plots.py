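"""Plot helpers for cohort analyses (histograms, sorted-score curves,
dose-scan lines).  All functions save to a file and return the path."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def score_histogram(theta_bars, path, bins=30, title="Adapted angular metric"):
    theta_bars = np.asarray(theta_bars, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(theta_bars, bins=bins, color="steelblue", edgecolor="white")
    mu, sigma = theta_bars.mean(), theta_bars.std()
    ax.axvline(mu, color="k", ls="--", label=f"μ = {mu:.2f}°")
    ax.axvline(mu + sigma, color="gray", ls=":", label=f"μ ± σ (σ = {sigma:.2f}°)")
    ax.axvline(max(mu - sigma, 0), color="gray", ls=":")
    ax.set_xlabel("θ̄ (°)")
    ax.set_ylabel("circuits")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def sorted_scores(theta_bars, path, title="Circuits sorted by score"):
    theta_bars = np.sort(np.asarray(theta_bars, dtype=float))
    mu, sigma = theta_bars.mean(), theta_bars.std()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(theta_bars, ".", ms=4)
    for y, ls in ((mu, "--"), (mu + sigma, ":"), (max(mu - sigma, 0), ":")):
        ax.axhline(y, color="gray", ls=ls)
    ax.set_xlabel("circuit rank")
    ax.set_ylabel("θ̄ (°)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ratio_scan_lines(scan: pd.DataFrame, path, title="Recombinase dose scan"):
    """Plot mean θ̄ vs α scale, one line per circuit (scan as returned
    by :func:`bladesim.performance.ratio_scan`)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cid, grp in scan.groupby("circuit_id"):
        grp = grp.sort_values("alpha_scale", ascending=False)
        ax.plot(grp.alpha_scale, grp.mean_theta_bar, "o-", label=f"circuit {cid}")
    ax.set_xlabel("α scale (reporter:recombinase 1:scale)")
    ax.set_ylabel("mean θ̄ (°)")
    ax.invert_xaxis()
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
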