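"""Plot helpers for the pipeline's standard figures.

Three figure styles: LD decay (r² against distance, one line per
population), persistence of phase (per-bin Pearson r of signed LD for each
population pair), and the historical Ne trajectory (Ne against T = 1/(2c),
log-log).  All take the corresponding TSV-shaped DataFrames produced by the
analysis stages.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_ld_decay(curves: dict[str, pd.DataFrame], path: str | Path) -> None:
    """``curves``: population -> decay profile (bin_mid_bp, mean_r2)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pop, prof in sorted(curves.items()):
        ax.plot(prof["bin_mid_bp"] / 1e6, prof["mean_r2"], marker="o", ms=3, label=pop)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel("mean r²")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_curves(curves: dict[str, pd.DataFrame], path: str | Path) -> None:
    """``curves``: "A-B" pair label -> phase bins (bin_start_bp, pearson_r)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pair, bins in sorted(curves.items()):
        ok = bins.dropna(subset=["pearson_r"])
        mid = (ok["bin_start_bp"] + ok["bin_end_bp"]) / 2e6
        ax.plot(mid, ok["pearson_r"], marker="o", ms=3, label=pair)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel("correlation of signed r")
    ax.axhline(0, color="grey", lw=0.5)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ne_trajectory(trajectories: dict[str, pd.DataFrame], path: str | Path) -> None:
    """``trajectories``: population -> (T_generations, ne) points."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pop, traj in sorted(trajectories.items()):
        ax.plot(traj["T_generations"], traj["ne"], marker=".", ls="", label=pop)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("generations ago (T = 1/2c)")
    ax.set_ylabel("Ne")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
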