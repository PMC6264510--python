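"""Figure-style plots: NMDS scatter with same-web links, silhouette
profile, relatedness report, correlogram, and stacked ancestry bars.

All functions write files and never open a display (Agg backend), so the
pipeline stays headless-safe.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .marker_data import MarkerMatrix
from .ordination import NMDSResult
from .partitioning import SilhouetteProfile


def plot_nmds(
    res: NMDSResult, meta: pd.DataFrame, path, dims: tuple[int, int] = (0, 1)
) -> None:
    """2-D NMDS scatter; individuals from the same web are linked."""
    x, y = res.configuration[:, dims[0]], res.configuration[:, dims[1]]
    fig, ax = plt.subplots(figsize=(6, 5))
    webs = meta["web_id"].to_numpy()
    cmap = plt.get_cmap("tab20")
    for i, web in enumerate(pd.unique(webs)):
        idx = np.flatnonzero(webs == web)
        color = cmap(i % 20)
        ax.scatter(x[idx], y[idx], s=18, color=color, label=str(web))
        for a in idx:
            for b in idx:
                if a < b:
                    ax.plot(x[[a, b]], y[[a, b]], color=color, lw=0.4, alpha=0.5)
    ax.set_xlabel(f"NMDS {dims[0] + 1}")
    ax.set_ylabel(f"NMDS {dims[1] + 1}")
    ax.set_title(f"NMDS (stress = {res.stress:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_silhouette_profile(profile: SilhouetteProfile, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.candidates, profile.scores, "o-", color="steelblue")
    ax.axvline(profile.optimal_c, ls="--", color="gray")
    ax.set_xlabel("number of clusters C")
    ax.set_ylabel("average silhouette score")
    ax.set_title(f"optimal C = {profile.optimal_c} ({profile.linkage_method} linkage)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_relatedness(table: pd.DataFrame, path) -> None:
    """Per-web mean relatedness with bootstrap CI bars and the permutation
    null band (red dashed); * above webs significantly higher, # lower."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(table)), 4))
    xs = np.arange(len(table))
    ax.plot(xs, table["null_lo"], "r--", lw=1)
    ax.plot(xs, table["null_hi"], "r--", lw=1)
    ax.errorbar(
        xs,
        table["mean_r"],
        yerr=[table["mean_r"] - table["boot_lo"], table["boot_hi"] - table["mean_r"]],
        fmt="_",
        color="royalblue",
        capsize=3,
    )
    for x, (flag, hi) in enumerate(zip(table["flag"], table["boot_hi"])):
        if flag == "higher":
            ax.annotate("*", (x, hi), ha="center", fontsize=14)
        elif flag == "lower":
            ax.annotate("#", (x, hi), ha="center", fontsize=10)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xticks(xs, table["web_id"], rotation=90)
    ax.set_ylabel("mean pairwise relatedness")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlogram(table: pd.DataFrame, path) -> None:
    """r per distance class (blue) with bootstrap error bars and the
    permutation null CI (red dashed)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.arange(len(table))
    ax.plot(xs, table["null_lo"], "r--", lw=1)
    ax.plot(xs, table["null_hi"], "r--", lw=1)
    ax.errorbar(
        xs,
        table["r"],
        yerr=[table["r"] - table["boot_lo"], table["boot_hi"] - table["r"]],
        fmt="o-",
        color="royalblue",
        capsize=3,
    )
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xticks(xs, [f"{b:g}" for b in table["class_upper_m"]])
    ax.set_xlabel("distance class upper bound (m)")
    ax.set_ylabel("autocorrelation r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ancestry_bars(q: np.ndarray, meta: pd.DataFrame, path) -> None:
    """Stacked per-individual ancestry proportions, ordered by web."""
    order = np.argsort(meta["web_id"].to_numpy(), kind="stable")
    q = np.asarray(q)[order]
    fig, ax = plt.subplots(figsize=(max(5, 0.08 * len(q)), 3))
    bottom = np.zeros(len(q))
    for k in range(q.shape[1]):
        ax.bar(np.arange(len(q)), q[:, k], bottom=bottom, width=1.0)
        bottom += q[:, k]
    ax.set_xlim(-0.5, len(q) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry proportion")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_all(out_dir, matrix: MarkerMatrix, meta: pd.DataFrame,
             nmds_res: NMDSResult, profile: SilhouetteProfile) -> None:
    out = Path(out_dir)
    plot_nmds(nmds_res, meta, out / "nmds.png")
    plot_silhouette_profile(profile, out / "silhouette.png")
    rel = out / "relatedness_report.tsv"
    if rel.exists():
        plot_relatedness(pd.read_csv(rel, sep="\t"), out / "relatedness.png")
    for f in out.glob("correlogram_*.tsv"):
        plot_correlogram(pd.read_csv(f, sep="\t"), f.with_suffix(".png"))
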