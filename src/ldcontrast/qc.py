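"""Per-population SNP and sample quality control.

Filters and defaults follow standard chip-genotyping practice: minor allele
frequency >= 5%, genotype call rate >= 90% per SNP and per sample, a
Hardy-Weinberg 1-df goodness-of-fit test at p > 1e-6, and pruning of close
relatives/duplicates at a genomic kinship above 0.8.  The kinship is the
frequency-weighted (Leutenegger-style) estimator, which has expectation 1
for duplicates and 0 for unrelated individuals under HWE.

The filter pass runs samples -> SNPs -> relatedness and is repeated until a
fixed point, so the output jointly satisfies every threshold and
``apply_qc`` is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dataset import DatasetError, GenotypeDataset


@dataclass
class QCConfig:
    """Thresholds for :func:`apply_qc`.

    Attributes
    ----------
    maf_min : minimum minor allele frequency (fraction).
    snp_call_min : minimum per-SNP genotype call rate.
    sample_call_min : minimum per-sample genotype call rate.
    hwe_p_min : SNPs with HWE p-value <= this are removed.
    ibs_max : kinship above which one of a sample pair is pruned.
    """

    maf_min: float = 0.05
    snp_call_min: float = 0.90
    sample_call_min: float = 0.90
    hwe_p_min: float = 1e-6
    ibs_max: float = 0.8

    def __post_init__(self):
        for name in ("maf_min", "snp_call_min", "sample_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.hwe_p_min < 1.0:
            raise ValueError("hwe_p_min must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "QCConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class QCReport:
    """Tally of what each filter removed.

    A record removed by multiple criteria is attributed to the first filter
    applied in the pass order (sample call rate, SNP call rate, MAF, HWE,
    relatedness).
    """

    population: str
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    removed_by_filter: dict[str, int] = field(default_factory=dict)
    removed_sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_in", self.n_samples_in), ("samples_out", self.n_samples_out),
                ("snps_in", self.n_snps_in), ("snps_out", self.n_snps_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_filter.items()]
        return pd.DataFrame(rows, columns=["quantity", "count"]).assign(
            population=self.population
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


FILTER_ORDER = ("sample_call_rate", "snp_call_rate", "maf", "hwe", "relatedness")


# ---------------------------------------------------------------------------
# per-marker statistics
# ---------------------------------------------------------------------------

def compute_maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column; NaN if all missing."""
    col = np.asarray(dosage_column, dtype=float)
    if col.size == 0:
        raise ValueError("empty dosage column")
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return float("nan")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def maf_vector(dosages: np.ndarray) -> np.ndarray:
    """Vectorized :func:`compute_maf` over matrix columns."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided p-value of the 1-df Hardy-Weinberg goodness-of-fit test.

    The z-test on genotype frequencies and the 1-df chi-square test are the
    same two-sided test (z^2 = chi^2).  Monomorphic input returns p = 1.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Per-column HWE p-values (vectorized over markers)."""
    n_aa = np.nansum(dosages == 0, axis=0).astype(float)
    n_ab = np.nansum(dosages == 1, axis=0).astype(float)
    n_bb = np.nansum(dosages == 2, axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    out = np.ones(dosages.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n_ab + 2 * n_bb) / (2 * n)
        poly = (n > 0) & (p > 0) & (p < 1)
        exp = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
        obs = np.stack([n_aa, n_ab, n_bb])
        chi2 = np.where(poly, ((obs - exp) ** 2 / np.where(exp > 0, exp, 1)).sum(axis=0), 0.0)
    out[poly] = stats.chi2.sf(chi2[poly], df=1)
    return out


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def ibs_kinship(dataset: GenotypeDataset) -> np.ndarray:
    """Frequency-weighted genomic kinship matrix.

    ``K[i, j]`` is the mean over markers (non-missing in both samples) of
    ``(g_i - 2p)(g_j - 2p) / (2p(1-p))`` with ``p`` the sample allele_b
    frequency.  Monomorphic markers contribute nothing; an error is raised
    if every marker is skipped.
    """
    if dataset.n_samples < 2:
        raise DatasetError("kinship needs at least two samples")
    g = dataset.dosages
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.any():
        raise DatasetError("no polymorphic markers for kinship")
    g = g[:, keep]
    p = p[keep]
    w = 1.0 / np.sqrt(2.0 * p * (1.0 - p))
    z = (g - 2.0 * p) * w
    mask = ~np.isnan(z)
    z0 = np.where(mask, z, 0.0)
    num = z0 @ z0.T
    cnt = mask.astype(float) @ mask.astype(float).T
    if (cnt == 0).any():
        raise DatasetError("some sample pairs share no genotyped marker")
    k = num / cnt
    return (k + k.T) / 2.0


def prune_related(
    dataset: GenotypeDataset, kinship: np.ndarray, ibs_max: float
) -> tuple[GenotypeDataset, list[str]]:
    """Greedily remove one member of every sample pair with kinship above
    ``ibs_max``; the member with the lower call rate loses, ties broken by
    removing the lexicographically later id."""
    n = dataset.n_samples
    if kinship.shape != (n, n):
        raise ValueError("kinship dimensions do not match dataset")
    call = dataset.call_rate_samples()
    active = np.ones(n, dtype=bool)
    removed: list[str] = []
    k = kinship.copy()
    np.fill_diagonal(k, -np.inf)
    while True:
        sub = np.where(np.outer(active, active), k, -np.inf)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= ibs_max:
            break
        if call[i] != call[j]:
            drop = i if call[i] < call[j] else j
        else:
            drop = i if dataset.sample_ids[i] > dataset.sample_ids[j] else j
        active[drop] = False
        removed.append(dataset.sample_ids[drop])
    return dataset.select_samples(active), removed


# ---------------------------------------------------------------------------
# the full pass
# ---------------------------------------------------------------------------

def _one_pass(ds: GenotypeDataset, cfg: QCConfig):
    tallies = dict.fromkeys(FILTER_ORDER, 0)
    removed_samples: list[str] = []

    keep = ds.call_rate_samples() >= cfg.sample_call_min
    tallies["sample_call_rate"] = int((~keep).sum())
    removed_samples += [s for s, k in zip(ds.sample_ids, keep) if not k]
    ds = ds.select_samples(keep)
    if ds.n_samples == 0:
        raise DatasetError("all samples removed by call-rate filter")

    keep = ds.call_rate_markers() >= cfg.snp_call_min
    tallies["snp_call_rate"] = int((~keep).sum())
    ds = ds.select_markers(keep)

    with np.errstate(invalid="ignore"):
        maf = maf_vector(ds.dosages)
    keep = np.nan_to_num(maf, nan=-1.0) >= cfg.maf_min
    tallies["maf"] = int((~keep).sum())
    ds = ds.select_markers(keep)

    if ds.n_markers:
        keep = hwe_pvalues(ds.dosages) > cfg.hwe_p_min
        tallies["hwe"] = int((~keep).sum())
        ds = ds.select_markers(keep)
    if ds.n_markers == 0:
        raise DatasetError("all SNPs removed by QC filters")

    if ds.n_samples >= 2:
        ds, rem = prune_related(ds, ibs_kinship(ds), cfg.ibs_max)
        tallies["relatedness"] = len(rem)
        removed_samples += rem
    return ds, tallies, removed_samples


def apply_qc(
    dataset: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC pass (samples -> SNPs -> relatedness), repeated until
    a fixed point so every threshold holds jointly on the output."""
    cfg = config or QCConfig()
    ds = dataset
    total = dict.fromkeys(FILTER_ORDER, 0)
    removed_samples: list[str] = []
    attributed: set[str] = set()
    while True:
        ds_next, tallies, rem = _one_pass(ds, cfg)
        for s in rem:
            if s not in attributed:
                attributed.add(s)
                removed_samples.append(s)
        changed = ds_next.n_samples != ds.n_samples or ds_next.n_markers != ds.n_markers
        for k in FILTER_ORDER:
            total[k] += tallies[k]
        ds = ds_next
        if not changed:
            break
    report = QCReport(
        population=dataset.population,
        n_samples_in=dataset.n_samples,
        n_samples_out=ds.n_samples,
        n_snps_in=dataset.n_markers,
        n_snps_out=ds.n_markers,
        removed_by_filter=total,
        removed_sample_ids=removed_samples,
    )
    return ds, report
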