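"""Kinship-based population structure via classical multidimensional scaling.

The genomic kinship matrix is converted to squared Euclidean distances
(D2[i,j] = K[ii] + K[jj] - 2 K[ij]) and embedded by Torgerson's classical
MDS: double-centre, eigendecompose, keep the top positive-eigenvalue axes.
Negative eigenvalues (non-Euclidean noise in the kinship estimate) are
dropped from the coordinates and from the explained-variance denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MdsResult:
    """Classical-MDS embedding.

    ``coordinates`` column ``i`` is the i-th eigenvector scaled by
    ``sqrt(eigenvalue_i)``; ``explained_fraction[i]`` is eigenvalue ``i``
    over the sum of positive eigenvalues.
    """

    coordinates: np.ndarray
    explained_fraction: np.ndarray
    eigenvalues: np.ndarray

    def to_frame(self, sample_ids=None, population=None) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"dim{i + 1}" for i in range(k)]
        )
        if sample_ids is not None:
            df.insert(0, "sample_id", list(sample_ids))
        if population is not None:
            df.insert(1, "population", list(population))
        return df


def kinship_to_sq_distance(kinship: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances implied by a kinship matrix.

    Negative results (possible with a noisy, non-PSD estimate) are clipped
    to zero with a warning; the diagonal is exactly zero.
    """
    k = np.asarray(kinship, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("kinship must be a square matrix")
    diag = np.diag(k)
    d2 = diag[:, None] + diag[None, :] - 2.0 * k
    if (d2 < -1e-12).any():
        warnings.warn("negative squared distances clipped to 0")
    d2 = np.clip(d2, 0.0, None)
    np.fill_diagonal(d2, 0.0)
    return d2


def classical_mds(sq_distance: np.ndarray, k: int) -> MdsResult:
    """Torgerson classical MDS of a squared-distance matrix.

    Sign convention: each coordinate column is flipped so its
    largest-magnitude entry is positive.  If fewer than ``k`` positive
    eigenvalues exist, the coordinates are padded with zero columns and a
    warning is issued.
    """
    d2 = np.asarray(sq_distance, dtype=float)
    n = d2.shape[0]
    if d2.ndim != 2 or d2.shape[1] != n:
        raise ValueError("squared-distance matrix must be square")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} must be in [1, n-1]")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = max(1e-10, 1e-10 * abs(vals[0])) if n else 0.0
    n_pos = int((vals > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; coordinates padded with zeros"
        )
    coords = np.zeros((n, k))
    coords[:, :k_eff] = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for c in range(k_eff):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    pos_sum = vals[:n_pos].sum()
    explained = np.zeros(k)
    if pos_sum > 0:
        explained[:k_eff] = vals[:k_eff] / pos_sum
    return MdsResult(coordinates=coords, explained_fraction=explained,
                     eigenvalues=vals)
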