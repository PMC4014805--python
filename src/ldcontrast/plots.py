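"""Plot helpers: LD-decay curves, MDS scatter, and genome-wide score tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .ld_stats import LdDecayCurve
from .popstructure import MdsResult
from .varld_core import VarLDTrack


def plot_ld_decay(curves: list[LdDecayCurve], path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        mid = (c.bin_edges[:-1] + c.bin_edges[1:]) / 2.0 / 1000.0
        ax.plot(mid, c.mean_r2, marker="o", ms=3, label=c.population)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mds(result: MdsResult, populations: list[str], path) -> None:
    df = pd.DataFrame({
        "dim1": result.coordinates[:, 0],
        "dim2": result.coordinates[:, 1],
        "population": populations,
    })
    fig, ax = plt.subplots(figsize=(5, 5))
    for pop, grp in df.groupby("population"):
        ax.scatter(grp["dim1"], grp["dim2"], s=12, label=pop)
    ax.set_xlabel(f"dim 1 ({100 * result.explained_fraction[0]:.1f}%)")
    ax.set_ylabel(f"dim 2 ({100 * result.explained_fraction[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_track(track: VarLDTrack, path, thresholds: dict[float, float] | None = None
               ) -> None:
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in track.scores.groupby("chromosome", sort=False):
        x = grp["mid_bp"].to_numpy() + offset
        ax.plot(x, grp["std_score"], ".", ms=2)
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max()
    if thresholds:
        for pct, thr in thresholds.items():
            ax.axhline(thr, ls="--", lw=0.8, color="grey")
            ax.annotate(f"{pct}%", (0, thr), fontsize=7)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("standardized score")
    ax.set_title(track.comparison_label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
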