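"""Two-population diploid SNP simulator with implanted selective sweeps.

The generator uses a founder-copying (haplotype-mosaic) model: each
population has a pool of founder haplotypes whose alleles are drawn at the
shared per-marker allele frequencies, and each sample haplotype is a mosaic
of founders with a per-marker-interval switch probability.  A lower switch
probability yields slower LD decay, so the two populations can mimic the
slow-decay / fast-decay contrast seen between cattle subspecies.  A
selective sweep is realized as a regional collapse of the copying pool to a
small residual founder subset in one population: haplotype diversity drops
and regional LD rises, while markers where the residual founders agree
become monomorphic there (and fall to the MAF filter, as on a real chip).
The residual pool never goes below two founders, so some markers always
stay polymorphic inside the sweep.

Everything is reproducible from the config seed, and the implanted sweeps
are returned as truth records for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import GenotypeDataset, marker_table


@dataclass(frozen=True)
class SweepSpec:
    """Where and how a sweep is implanted; doubles as the truth record."""

    chromosome: str
    start_bp: int
    end_bp: int
    population: str
    residual_founders: int = 2

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("sweep start_bp must be <= end_bp")
        if self.residual_founders < 2:
            raise ValueError(
                "residual founder pool must be >= 2 so sweep markers can stay "
                "polymorphic (LD contrast is blind to fixed markers)"
            )


SweepTruth = SweepSpec


def _default_sweeps() -> tuple[SweepSpec, ...]:
    return (SweepSpec("1", 20_000_000, 20_300_000, "POP1", 2),)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for :func:`simulate_pair`.

    Defaults describe the standard scenario used throughout: two cohorts of
    150 samples, two chromosomes of 5,000 markers at a mean spacing of
    7,900 bp (a high-density bovine chip averages ~7.9 kb between SNPs), 30
    founder haplotypes per population, founder-switch probabilities 0.05
    (slow LD decay) vs 0.15 (fast decay), founder allele frequencies uniform
    on [0.1, 0.9], 0.2% missing genotypes, and one 300-kb sweep in POP1
    whose copying pool collapses to 2 founders.
    """

    n_samples: tuple[int, int] = (150, 150)
    population_labels: tuple[str, str] = ("POP1", "POP2")
    n_chromosomes: int = 2
    markers_per_chromosome: int = 5_000
    mean_spacing_bp: int = 7_900
    n_founders: int = 30
    switch_prob: tuple[float, float] = (0.05, 0.15)
    maf_floor: float = 0.1
    missing_rate: float = 0.002
    n_duplicates: tuple[int, int] = (0, 0)
    sweeps: tuple[SweepSpec, ...] = field(default_factory=_default_sweeps)
    seed: int = 0

    def __post_init__(self):
        for p in (*self.switch_prob, self.missing_rate, self.maf_floor):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_founders < 2:
            raise ValueError("need at least two founder haplotypes")
        if self.maf_floor >= 0.5:
            raise ValueError("maf_floor must be < 0.5")
        span = self.markers_per_chromosome * self.mean_spacing_bp * 2
        chroms = {str(c + 1) for c in range(self.n_chromosomes)}
        for sw in self.sweeps:
            if sw.chromosome not in chroms:
                raise ValueError(f"sweep on unknown chromosome {sw.chromosome}")
            if sw.end_bp > span:
                raise ValueError("sweep interval outside the chromosome span")
            if sw.population not in self.population_labels:
                raise ValueError(f"sweep population {sw.population} unknown")
            if sw.residual_founders >= self.n_founders:
                raise ValueError(
                    "residual founder pool must be smaller than the "
                    "background founder pool"
                )


BASES = np.array(["A", "C", "G", "T"])


def _positions(rng: np.random.Generator, m: int, mean_spacing: int) -> np.ndarray:
    gaps = np.maximum(1, rng.exponential(mean_spacing, size=m).astype(np.int64))
    return np.cumsum(gaps)


def _founder_paths(
    rng: np.random.Generator, n_hap: int, m: int, n_founders: int, switch: float
) -> np.ndarray:
    """Founder index per haplotype and marker under the mosaic model."""
    choice = rng.integers(0, n_founders, size=(n_hap, m))
    sw = np.empty((n_hap, m), dtype=bool)
    sw[:, 0] = True
    sw[:, 1:] = rng.random((n_hap, m - 1)) < switch
    cols = np.arange(m)
    last_switch = np.maximum.accumulate(np.where(sw, cols, 0), axis=1)
    return np.take_along_axis(choice, last_switch, axis=1)


def simulate_pair(
    config: SimConfig,
) -> tuple[GenotypeDataset, GenotypeDataset, list[SweepTruth]]:
    """Simulate the two-population cohort described by ``config``.

    Returns the two datasets plus the truth records of the implanted
    sweeps.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m_per = config.markers_per_chromosome
    chrom_labels = [str(c + 1) for c in range(config.n_chromosomes)]

    records = []
    positions: dict[str, np.ndarray] = {}
    for chrom in chrom_labels:
        pos = _positions(rng, m_per, config.mean_spacing_bp)
        positions[chrom] = pos
        pair_idx = rng.integers(0, 4, size=m_per)
        other = (pair_idx + 1 + rng.integers(0, 3, size=m_per)) % 4
        for k in range(m_per):
            a1, a2 = sorted((BASES[pair_idx[k]], BASES[other[k]]))
            records.append((f"snp_{chrom}_{k}", chrom, int(pos[k]), a1, a2))
    markers = marker_table(records)
    m_total = len(markers)

    freqs = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m_total)

    datasets = []
    for pop_i, label in enumerate(config.population_labels):
        n = config.n_samples[pop_i]
        founders = (rng.random((config.n_founders, m_total)) < freqs).astype(np.int8)
        paths = _founder_paths(
            rng, 2 * n, m_total, config.n_founders, config.switch_prob[pop_i]
        )
        # regional pool collapse for sweeps in this population
        for sw in config.sweeps:
            if sw.population != label:
                continue
            in_sweep = (
                (markers["chromosome"] == sw.chromosome)
                & (markers["position_bp"] >= sw.start_bp)
                & (markers["position_bp"] <= sw.end_bp)
            ).to_numpy()
            paths[:, in_sweep] = paths[:, in_sweep] % sw.residual_founders
        hap = founders[paths, np.arange(m_total)]
        geno = (hap[0::2] + hap[1::2]).astype(float)

        n_dup = config.n_duplicates[pop_i]
        if n_dup:
            if 2 * n_dup > n:
                raise ValueError("too many duplicates requested")
            geno[n - n_dup:] = geno[:n_dup]

        if config.missing_rate > 0:
            miss = rng.random(geno.shape) < config.missing_rate
            geno[miss] = np.nan

        sample_ids = [f"{label}_s{i:04d}" for i in range(n)]
        datasets.append(GenotypeDataset(sample_ids, label, markers.copy(), geno))

    return datasets[0], datasets[1], list(config.sweeps)


# ---------------------------------------------------------------------------
# QC violation fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViolationSpec:
    """How many records of each kind :func:`implant_qc_violations` injects."""

    low_call_samples: int = 0
    low_call_snps: int = 0
    low_maf_snps: int = 0
    hwe_snps: int = 0
    duplicate_pairs: int = 0


def implant_qc_violations(
    dataset: GenotypeDataset, spec: ViolationSpec, seed: int
) -> tuple[GenotypeDataset, dict]:
    """Deterministically inject QC-violating records into a clean dataset.

    Returns the modified dataset and a manifest naming the affected sample
    and marker ids per category.  Low-call records get 15% missingness
    (below the 90% call-rate floor), low-MAF SNPs keep a single heterozygote
    (MAF ~ 1/2n), HWE violations are heterozygote-free half/half columns
    (chi-square = n), and duplicate pairs are exact row copies.
    """
    n, m = dataset.dosages.shape
    need_samples = spec.low_call_samples + 2 * spec.duplicate_pairs
    need_snps = spec.low_call_snps + spec.low_maf_snps + spec.hwe_snps
    if need_samples > n or need_snps > m:
        raise ValueError("not enough samples/markers to host the violations")
    rng = np.random.default_rng(seed)
    sample_pick = rng.choice(n, size=need_samples, replace=False)
    snp_pick = rng.choice(m, size=need_snps, replace=False)
    d = dataset.dosages.copy()
    manifest: dict[str, list] = {
        "low_call_samples": [], "low_call_snps": [], "low_maf_snps": [],
        "hwe_snps": [], "duplicate_pairs": [],
    }

    si = iter(sample_pick)
    ci = iter(snp_pick)
    for _ in range(spec.low_call_snps):
        j = next(ci)
        rows = rng.choice(n, size=max(1, int(np.ceil(0.15 * n))), replace=False)
        d[rows, j] = np.nan
        manifest["low_call_snps"].append(dataset.markers["marker_id"].iloc[j])
    for _ in range(spec.low_maf_snps):
        j = next(ci)
        d[:, j] = 0.0
        d[rng.integers(0, n), j] = 1.0
        manifest["low_maf_snps"].append(dataset.markers["marker_id"].iloc[j])
    for _ in range(spec.hwe_snps):
        j = next(ci)
        half = n // 2
        col = np.concatenate([np.zeros(half), 2.0 * np.ones(n - half)])
        d[:, j] = rng.permutation(col)
        manifest["hwe_snps"].append(dataset.markers["marker_id"].iloc[j])
    for _ in range(spec.duplicate_pairs):
        src, dst = next(si), next(si)
        d[dst, :] = d[src, :]
        manifest["duplicate_pairs"].append(
            (dataset.sample_ids[src], dataset.sample_ids[dst])
        )
    for _ in range(spec.low_call_samples):
        i = next(si)
        cols = rng.choice(m, size=max(1, int(np.ceil(0.15 * m))), replace=False)
        d[i, cols] = np.nan
        manifest["low_call_samples"].append(dataset.sample_ids[i])

    out = GenotypeDataset(dataset.sample_ids, dataset.population,
                          dataset.markers, d, _validated=True)
    return out, manifest
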