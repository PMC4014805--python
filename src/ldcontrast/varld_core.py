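"""Windowed eigen-score contrast of LD patterns between two populations.

For each sliding window of ``window_size`` SNPs (default 50, step 1) a
signed-r^2 correlation matrix is built per population.  The two matrices are
compared through their eigenvalue spectra: the raw window score is the L1
distance between the descending-sorted eigenvalue vectors,

    score = sum_i | lambda_a(i) - lambda_b(i) |.

Both matrices have unit diagonal, so their eigenvalues each sum to the
window size and a plain difference of traces would vanish identically; the
absolute form is what makes the score a magnitude of LD-pattern
dissimilarity (and an L1 metric on ranked spectra).  Raw scores are then
standardized genome-wide to mean 0, sd 1 within a comparison, and Monte
Carlo significance is available by permuting individuals between the two
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import DatasetError, GenotypeDataset
from .ld_stats import signed_r2_matrix

TRACK_COLUMNS = [
    "chromosome", "first_snp_index", "first_snp_bp", "last_snp_bp",
    "mid_bp", "raw_score", "std_score",
]


@dataclass
class VarLDTrack:
    """Ordered per-window scores for one population comparison.

    ``scores`` is a DataFrame with columns ``chromosome, first_snp_index,
    first_snp_bp, last_snp_bp, mid_bp, raw_score, std_score``;
    ``first_snp_index`` indexes into the shared marker map.  ``std_score``
    is NaN until :func:`standardize` has been applied.
    """

    comparison_label: str
    window_size: int
    step: int
    scores: pd.DataFrame

    @property
    def is_standardized(self) -> bool:
        return bool(np.isfinite(self.scores["std_score"]).all()) and len(self.scores) > 0

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, comparison_label: str, window_size: int, step: int
                 ) -> "VarLDTrack":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        return cls(comparison_label, window_size, step, df[TRACK_COLUMNS])


# ---------------------------------------------------------------------------
# window-level pieces
# ---------------------------------------------------------------------------

def window_corr_matrix(
    dataset: GenotypeDataset, start_index: int, window_size: int
) -> np.ndarray:
    """Signed-r^2 correlation matrix of one window of consecutive markers.

    The window must lie within one chromosome and every marker must be
    polymorphic; a monomorphic column raises an error naming the marker.
    """
    stop = start_index + window_size
    if start_index < 0 or stop > dataset.n_markers:
        raise IndexError("window outside the marker range")
    chroms = dataset.markers["chromosome"].iloc[start_index:stop]
    if chroms.nunique() > 1:
        raise DatasetError("window spans a chromosome boundary")
    x = dataset.dosages[:, start_index:stop]
    mat = signed_r2_matrix(x)
    bad = np.isnan(np.diag(mat))
    if bad.any():
        mid = dataset.markers["marker_id"].iloc[start_index + int(np.flatnonzero(bad)[0])]
        raise DatasetError(
            f"monomorphic marker {mid} inside window; filter before scanning"
        )
    np.fill_diagonal(mat, 1.0)
    return np.nan_to_num(mat, nan=0.0)


def raw_varld_score(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """L1 distance between the descending-ranked eigenvalue spectra of two
    symmetric matrices."""
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    ev_a = np.sort(np.linalg.eigvalsh(a))[::-1]
    ev_b = np.sort(np.linalg.eigvalsh(b))[::-1]
    return float(np.abs(ev_a - ev_b).sum())


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def _check_scannable(a: GenotypeDataset, b: GenotypeDataset) -> None:
    if not a.same_map(b):
        raise ValueError("datasets must share an identical marker map; "
                         "run intersect_common_snps first")


def _chromosome_blocks(markers: pd.DataFrame):
    chrom = markers["chromosome"].to_numpy()
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            yield chrom[start], start, i
            start = i


def _window_eigs(
    x: np.ndarray, window_size: int, step: int, strict: bool = True
) -> np.ndarray:
    """Descending-sorted eigenvalues of the signed-r^2 matrix of every
    window over the columns of ``x``; shape (n_windows, window_size).

    In strict mode a monomorphic column raises; in lenient mode (used for
    permutation replicates, where a rare allele can land entirely in one
    group) the column's correlations are treated as zero.
    """
    m = x.shape[1]
    starts = range(0, m - window_size + 1, step)
    out = np.empty((len(starts), window_size))
    for wi, s in enumerate(starts):
        mat = signed_r2_matrix(x[:, s:s + window_size])
        if strict and np.isnan(np.diag(mat)).any():
            j = int(np.flatnonzero(np.isnan(np.diag(mat)))[0])
            raise DatasetError(
                f"monomorphic column at window offset {s + j}; "
                "filter markers before scanning"
            )
        np.fill_diagonal(mat, 1.0)
        mat = np.nan_to_num(mat, nan=0.0)
        out[wi] = np.sort(np.linalg.eigvalsh(mat))[::-1]
    return out


def _raw_scores_frame(
    dos_a: np.ndarray, dos_b: np.ndarray, markers: pd.DataFrame,
    window_size: int, step: int, strict: bool = True,
) -> pd.DataFrame:
    rows = []
    for chrom, lo, hi in _chromosome_blocks(markers):
        m = hi - lo
        if m < window_size:
            warnings.warn(
                f"chromosome {chrom}: {m} markers < window size {window_size}; skipped"
            )
            continue
        ev_a = _window_eigs(dos_a[:, lo:hi], window_size, step, strict)
        ev_b = _window_eigs(dos_b[:, lo:hi], window_size, step, strict)
        raw = np.abs(ev_a - ev_b).sum(axis=1)
        pos = markers["position_bp"].to_numpy()[lo:hi]
        starts = np.arange(0, m - window_size + 1, step)
        first_bp = pos[starts]
        last_bp = pos[starts + window_size - 1]
        mid = np.rint((first_bp + last_bp) / 2.0).astype(np.int64)
        rows.append(pd.DataFrame({
            "chromosome": chrom,
            "first_snp_index": starts + lo,
            "first_snp_bp": first_bp,
            "last_snp_bp": last_bp,
            "mid_bp": mid,
            "raw_score": raw,
            "std_score": np.nan,
        }))
    if not rows:
        raise DatasetError("no chromosome has enough markers for one window")
    return pd.concat(rows, ignore_index=True)


def scan(
    a: GenotypeDataset,
    b: GenotypeDataset,
    window_size: int = 50,
    step: int = 1,
) -> VarLDTrack:
    """Sliding-window eigen-score scan of two datasets sharing a marker map.

    Windows are defined in SNP-index space (never crossing chromosome
    boundaries) at offsets 0, step, 2*step, ...; the window midpoint is the
    rounded mean of the first and last SNP positions.  Chromosomes with
    fewer than ``window_size`` markers are skipped with a warning.
    """
    _check_scannable(a, b)
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    df = _raw_scores_frame(a.dosages, b.dosages, a.markers, window_size, step)
    label = f"{a.population}/{b.population}"
    return VarLDTrack(label, window_size, step, df)


def standardize(track: VarLDTrack) -> VarLDTrack:
    """Centre and scale the raw scores genome-wide to mean 0, sd 1
    (sample sd, n-1 denominator)."""
    raw = track.scores["raw_score"].to_numpy()
    if len(raw) < 2:
        raise DatasetError("standardization needs at least two windows")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise DatasetError("degenerate track: all raw scores equal")
    df = track.scores.copy()
    df["std_score"] = (raw - raw.mean()) / sd
    return replace(track, scores=df)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permutation_null(
    a: GenotypeDataset,
    b: GenotypeDataset,
    n_perm: int,
    seed: int,
    window_size: int = 50,
    step: int = 1,
) -> pd.DataFrame:
    """Per-window empirical p-values from a label-permutation null.

    Individuals from both populations are pooled and randomly reassigned to
    two groups of the original sizes ``n_perm`` times; the p-value is
    ``(1 + #{permuted raw >= observed raw}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_scannable(a, b)
    observed = _raw_scores_frame(a.dosages, b.dosages, a.markers,
                                 window_size, step)
    obs = observed["raw_score"].to_numpy()
    pool = np.vstack([a.dosages, b.dosages])
    n_a = a.n_samples
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs), dtype=int)
    for _ in range(n_perm):
        order = rng.permutation(pool.shape[0])
        perm = _raw_scores_frame(
            pool[order[:n_a]], pool[order[n_a:]], a.markers, window_size, step,
            strict=False,
        )["raw_score"].to_numpy()
        exceed += perm >= obs
    out = observed[["chromosome", "first_snp_index", "first_snp_bp",
                    "last_snp_bp", "mid_bp", "raw_score"]].copy()
    out["p_value"] = (1.0 + exceed) / (n_perm + 1.0)
    return out
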