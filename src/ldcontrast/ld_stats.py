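"""Pairwise genotype LD statistics on unphased dosages (composite LD).

All correlations are Pearson correlations of dosage columns over
pairwise-complete samples; ``signed r^2`` is ``sign(r) * r^2``.  Pairs with
zero variance on the joint support (or fewer than two complete samples)
return ``NaN`` as a defined sentinel: it is treated as a zero contribution
in window means, while the scan's correlation matrices reject monomorphic
columns outright (they must be filtered upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset


# ---------------------------------------------------------------------------
# pair and matrix correlation
# ---------------------------------------------------------------------------

def genotype_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two dosage vectors over pairwise-complete
    entries; NaN if the joint support is degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def signed_r2(x: np.ndarray, y: np.ndarray) -> float:
    """``sign(r) * r^2`` for two dosage vectors."""
    r = genotype_r(x, y)
    return float(np.sign(r) * r * r) if np.isfinite(r) else r


def corr_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix of the columns of ``x``.

    Vectorized over all column pairs using masked cross-products, so it
    handles missing entries without a per-pair Python loop.  Degenerate
    pairs are NaN; the diagonal is 1 where the column is polymorphic.
    """
    x = np.asarray(x, dtype=float)
    m = (~np.isnan(x)).astype(float)
    w = np.where(np.isnan(x), 0.0, x)
    n = m.T @ m                      # joint support size per pair
    sx = w.T @ m                     # sum of x over the joint support
    sxx = (w * w).T @ m              # sum of x^2 over the joint support
    sxy = w.T @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_x = sxx / n - (sx / n) ** 2
        var_y = var_x.T
        r = cov / np.sqrt(var_x * var_y)
    r[n < 2] = np.nan
    bad = ~np.isfinite(r)
    r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return (r + r.T) / 2.0


def signed_r2_matrix(x: np.ndarray) -> np.ndarray:
    """Signed-r^2 matrix of the columns of ``x`` (sign(r) * r^2)."""
    r = corr_matrix(x)
    return np.sign(r) * r * r


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LdDecayCurve:
    """Mean r^2 binned by inter-SNP distance.

    ``bin_edges`` has one more entry than ``mean_r2``; bins are left-closed,
    right-open and contiguous from 0 to the maximum distance.
    """

    population: str
    bin_edges: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "population": self.population,
            "bin_start_bp": self.bin_edges[:-1].astype(int),
            "bin_end_bp": self.bin_edges[1:].astype(int),
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs.astype(int),
        })


def ld_decay(
    dataset: GenotypeDataset,
    max_dist_bp: int = 100_000,
    bin_width_bp: int = 10_000,
) -> LdDecayCurve:
    """LD decay curve: mean r^2 of all intra-chromosome SNP pairs within
    ``max_dist_bp``, binned by physical distance."""
    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    if edges[-1] < max_dist_bp:
        edges = np.append(edges, max_dist_bp)
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)

    markers = dataset.markers
    for chrom in dataset.chromosomes():
        idx = np.flatnonzero((markers["chromosome"] == chrom).to_numpy())
        pos = markers["position_bp"].to_numpy()[idx]
        g = dataset.dosages[:, idx]
        m = len(idx)
        for i in range(m - 1):
            jmax = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            if jmax <= i + 1:
                continue
            block = slice(i + 1, jmax)
            r = _corr_one_vs_block(g[:, i], g[:, block])
            r2 = r * r
            dist = pos[block] - pos[i]
            ok = np.isfinite(r2)
            if ok.any():
                b = np.minimum(np.searchsorted(edges, dist[ok], side="right") - 1,
                               nbins - 1)
                np.add.at(sums, b, r2[ok])
                np.add.at(counts, b, 1)
    if counts.sum() == 0:
        warnings.warn("no qualifying SNP pairs within max_dist_bp")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayCurve(dataset.population, edges, mean, counts)


def _corr_one_vs_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Pairwise-complete correlation of one column against a block."""
    mx = ~np.isnan(x)
    mb = ~np.isnan(block)
    ok = mx[:, None] & mb
    n = ok.sum(axis=0)
    x0 = np.where(np.isnan(x), 0.0, x)
    b0 = np.where(np.isnan(block), 0.0, block)
    sx = x0 @ ok
    sb = (b0 * ok).sum(axis=0)
    sxx = (x0 * x0) @ ok
    sbb = (b0 * b0 * ok).sum(axis=0)
    sxb = (x0[:, None] * b0 * ok).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxb / n - (sx / n) * (sb / n)
        vx = sxx / n - (sx / n) ** 2
        vb = sbb / n - (sb / n) ** 2
        r = cov / np.sqrt(vx * vb)
    r[(n < 2) | ~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# windowed mean r^2 (breed-assignment profile)
# ---------------------------------------------------------------------------

@dataclass
class R2Profile:
    """Sliding-window mean pairwise r^2; windows with fewer SNPs than the
    cutoff are discarded."""

    population: str
    windows: pd.DataFrame  # chromosome, start_bp, end_bp, mean_r2, n_snps

    def to_tsv(self, path) -> None:
        self.windows.assign(population=self.population).to_csv(
            path, sep="\t", index=False
        )


def mean_pairwise_r2(x: np.ndarray) -> float:
    """Mean r^2 over all column pairs; NaN sentinel pairs count as 0."""
    if x.shape[1] < 2:
        return float("nan")
    r = corr_matrix(x)
    r2 = np.nan_to_num(r * r, nan=0.0)
    iu = np.triu_indices(x.shape[1], k=1)
    return float(r2[iu].mean())


def windowed_mean_r2(
    dataset: GenotypeDataset,
    window_bp: int = 200_000,
    step_bp: int = 20_000,
    min_snps: int = 50,
) -> R2Profile:
    """Mean pairwise r^2 in sliding physical windows (defaults 200 kb
    windows, 20 kb step), discarding windows with fewer than ``min_snps``."""
    rows = []
    markers = dataset.markers
    for chrom in dataset.chromosomes():
        idx = np.flatnonzero((markers["chromosome"] == chrom).to_numpy())
        pos = markers["position_bp"].to_numpy()[idx]
        if len(pos) == 0:
            continue
        start = int(pos[0])
        last = int(pos[-1])
        while start <= last:
            end = start + window_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_snps = hi - lo
            if n_snps >= min_snps:
                sub = dataset.dosages[:, idx[lo:hi]]
                rows.append((chrom, start, end, mean_pairwise_r2(sub), int(n_snps)))
            start += step_bp
    return R2Profile(
        dataset.population,
        pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                    "mean_r2", "n_snps"]),
    )
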