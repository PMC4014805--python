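"""Genotype containers shared by every stage of the pipeline.

A :class:`GenotypeDataset` holds a samples x markers dosage matrix for one
labelled population together with its marker map.  Dosages count copies of
``allele_b`` (by convention the lexicographically later allele character) and
are stored as floats so that missing genotypes can be ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


def marker_table(records: Sequence[tuple]) -> pd.DataFrame:
    """Build a marker map DataFrame from (id, chrom, bp, allele_a, allele_b) tuples."""
    df = pd.DataFrame(list(records), columns=MARKER_COLUMNS)
    df["chromosome"] = df["chromosome"].astype(str)
    df["position_bp"] = df["position_bp"].astype(np.int64)
    return df


def _chromosome_sort_key(label: str):
    # numeric chromosome labels sort numerically, others lexicographically after
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclass
class GenotypeDataset:
    """Diploid dosage matrix for one population.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    population
        Label of the population the samples belong to.
    markers
        Marker map with columns ``marker_id, chromosome, position_bp,
        allele_a, allele_b``; one row per matrix column.
    dosages
        ``(n_samples, n_markers)`` float array with entries in ``{0, 1, 2}``
        counting copies of ``allele_b``; ``NaN`` marks a missing genotype.
    """

    sample_ids: list[str]
    population: str
    markers: pd.DataFrame
    dosages: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if not self._validated:
            self.validate()
            self._validated = True

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape if self.dosages.ndim == 2 else (len(self.dosages), -1)
        if self.dosages.ndim != 2:
            raise DatasetError("dosages must be a 2-D matrix")
        if len(self.sample_ids) != n:
            raise DatasetError(
                f"{len(self.sample_ids)} sample ids but {n} dosage rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DatasetError("sample_ids are not unique")
        if list(self.markers.columns[:5]) != MARKER_COLUMNS:
            raise DatasetError(f"marker table must have columns {MARKER_COLUMNS}")
        if len(self.markers) != m:
            raise DatasetError(f"{len(self.markers)} markers but {m} dosage columns")
        if self.markers["marker_id"].duplicated().any():
            raise DatasetError("duplicate marker_id")
        if (self.markers["position_bp"] < 1).any():
            raise DatasetError("positions must be >= 1 (1-based)")
        if (self.markers["allele_a"] == self.markers["allele_b"]).any():
            bad = self.markers.loc[
                self.markers["allele_a"] == self.markers["allele_b"], "marker_id"
            ].iloc[0]
            raise DatasetError(f"allele_a == allele_b at marker {bad}")
        for _, pos in self.markers.groupby("chromosome", sort=False)["position_bp"]:
            d = np.diff(pos.to_numpy())
            if (d <= 0).any():
                raise DatasetError(
                    "marker positions must be strictly increasing within a chromosome"
                )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise DatasetError("dosage entries must be 0, 1, 2 or NaN")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def call_rate_samples(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def call_rate_markers(self) -> np.ndarray:
        """Fraction of non-missing genotypes per marker."""
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def select_samples(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            population=self.population,
            markers=self.markers,
            dosages=self.dosages[index, :],
            _validated=True,
        )

    def select_markers(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            sample_ids=self.sample_ids,
            population=self.population,
            markers=self.markers.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
            _validated=True,
        )

    def sort_markers(self) -> "GenotypeDataset":
        """Return a copy with markers sorted by (chromosome, position)."""
        keys = [
            (_chromosome_sort_key(c), p)
            for c, p in zip(self.markers["chromosome"], self.markers["position_bp"])
        ]
        order = sorted(range(len(keys)), key=keys.__getitem__)
        ds = self.select_markers(np.asarray(order, dtype=int))
        return replace(ds, _validated=False)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.markers["chromosome"]:
            seen.setdefault(c, None)
        return sorted(seen, key=_chromosome_sort_key)

    def same_map(self, other: "GenotypeDataset") -> bool:
        a = self.markers[["chromosome", "position_bp"]]
        b = other.markers[["chromosome", "position_bp"]]
        return len(a) == len(b) and bool((a.to_numpy() == b.to_numpy()).all())
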