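"""End-to-end orchestration: QC -> intersect -> structure -> decay -> scan
-> standardize -> call -> assign -> annotate -> coverage.

`run_comparison` is the in-memory engine for one population pair;
`run_pipeline` wraps it with file I/O and a machine-readable run manifest;
`run_comparisons` enumerates all unordered pairs of a multi-population
panel and marks signals shared across comparisons by interval overlap.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset
from .genotype_io import intersect_common_snps, read_bed_intervals, read_ped_map
from .ld_stats import ld_decay
from .popstructure import classical_mds, kinship_to_sq_distance
from .qc import QCConfig, apply_qc, ibs_kinship
from .signals import (SignalRegion, assign_population, call_signals,
                      coverage_summary, overlap_annotations,
                      percentile_threshold, regions_to_bed, regions_to_frame)
from .varld_core import VarLDTrack, scan, standardize

log = logging.getLogger("ldcontrast")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run over one population pair."""

    inputs: list[tuple[str, str, str]]  # (population label, ped path, map path)
    qc: QCConfig = field(default_factory=QCConfig)
    window_size: int = 50
    step: int = 1
    percentiles: tuple[float, ...] = (99.9, 99.99)
    gene_bed: str | None = None
    cnv_bed: str | None = None
    outdir: str = "results/run"
    seed: int = 0
    decay_max_dist_bp: int = 100_000
    decay_bin_width_bp: int = 10_000

    def __post_init__(self):
        for p in self.percentiles:
            if not 0.0 < p < 100.0:
                raise ValueError("percentiles must be in (0, 100)")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")


@dataclass
class ComparisonResult:
    """Everything one pairwise comparison produces, in memory."""

    label: str
    track: VarLDTrack
    thresholds: dict[float, float]
    regions: dict[float, list[SignalRegion]]
    decay: dict[str, pd.DataFrame]
    coverage: dict[float, tuple[int, float]]
    overlaps: pd.DataFrame | None = None
    a: GenotypeDataset | None = None
    b: GenotypeDataset | None = None


def chromosome_lengths_from(*datasets: GenotypeDataset) -> dict[str, int]:
    """Chromosome extents inferred as the maximum observed marker position."""
    lengths: dict[str, int] = {}
    for ds in datasets:
        for chrom, grp in ds.markers.groupby("chromosome", sort=False):
            lengths[chrom] = max(lengths.get(chrom, 0), int(grp["position_bp"].max()))
    return lengths


def run_comparison(
    a_qc: GenotypeDataset,
    b_qc: GenotypeDataset,
    window_size: int = 50,
    step: int = 1,
    percentiles: tuple[float, ...] = (99.9, 99.99),
    annotations: pd.DataFrame | None = None,
    compute_decay: bool = True,
) -> ComparisonResult:
    """Scan one QC'd population pair and call/assign signals.

    Inputs must already be quality controlled; markers are intersected and
    harmonized here, then restricted to markers polymorphic in both
    populations (LD contrast is undefined on monomorphic columns).
    """
    a, b = intersect_common_snps(a_qc, b_qc)
    poly = _jointly_polymorphic(a, b)
    a, b = a.select_markers(poly), b.select_markers(poly)
    log.info("%s/%s: %d shared polymorphic markers",
             a.population, b.population, a.n_markers)

    track = standardize(scan(a, b, window_size=window_size, step=step))
    thresholds, regions, coverage = {}, {}, {}
    lengths = chromosome_lengths_from(a, b)
    for pct in percentiles:
        thr = percentile_threshold(track, pct)
        regs = call_signals(track, thr)
        for r in regs:
            assign_population(r, a, b)
        thresholds[pct] = thr
        regions[pct] = regs
        coverage[pct] = coverage_summary(regs, lengths)
    decay = {}
    if compute_decay:
        for ds in (a, b):
            decay[ds.population] = ld_decay(ds).to_frame()
    overlaps = None
    if annotations is not None:
        widest = regions[min(percentiles)]
        overlaps = overlap_annotations(widest, annotations)
    return ComparisonResult(
        label=track.comparison_label, track=track, thresholds=thresholds,
        regions=regions, decay=decay, coverage=coverage, overlaps=overlaps,
        a=a, b=b,
    )


def _jointly_polymorphic(a: GenotypeDataset, b: GenotypeDataset) -> np.ndarray:
    keep = np.ones(a.n_markers, dtype=bool)
    for ds in (a, b):
        with np.errstate(invalid="ignore"):
            p = np.nanmean(ds.dosages, axis=0) / 2.0
        keep &= np.isfinite(p) & (p > 0) & (p < 1)
        # also require residual variance on the observed genotypes
        keep &= np.nanstd(ds.dosages, axis=0) > 0
    return keep


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline from PED/MAP inputs to tables on disk.

    Writes per-population QC reports, MDS coordinates, LD-decay curves, the
    standardized scan track, signal tables and BEDs per percentile,
    annotation overlaps, a coverage summary, and a manifest listing every
    output with a content digest.
    """
    if len(config.inputs) != 2:
        raise ValueError("run_pipeline drives one population pair; "
                         "use run_comparisons for a panel")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    datasets = []
    for label, ped, map_ in config.inputs:
        ds = read_ped_map(ped, map_, label)
        ds_qc, report = apply_qc(ds, config.qc)
        report.to_tsv(out / f"qc_report_{label}.tsv")
        log.info("QC %s: %d->%d samples, %d->%d SNPs", label,
                 report.n_samples_in, report.n_samples_out,
                 report.n_snps_in, report.n_snps_out)
        datasets.append(ds_qc)

    annotations = _load_annotations(config)
    result = run_comparison(
        datasets[0], datasets[1], config.window_size, config.step,
        config.percentiles, annotations,
    )

    # population structure on the combined panel over the shared markers
    combined = _stack(result.a, result.b)
    mds = classical_mds(kinship_to_sq_distance(ibs_kinship(combined)), k=2)
    coords = mds.to_frame(
        combined.sample_ids,
        [result.a.population] * result.a.n_samples
        + [result.b.population] * result.b.n_samples,
    )
    coords.to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)

    pd.concat(result.decay.values()).to_csv(out / "ld_decay.tsv", sep="\t",
                                            index=False)
    result.track.to_tsv(out / "scan_track.tsv")
    cov_rows = []
    for pct in config.percentiles:
        tag = f"p{pct:g}".replace(".", "_")
        regions_to_frame(result.regions[pct]).to_csv(
            out / f"signals_{tag}.tsv", sep="\t", index=False)
        regions_to_bed(result.regions[pct], out / f"signals_{tag}.bed")
        total, frac = result.coverage[pct]
        cov_rows.append((pct, result.thresholds[pct], len(result.regions[pct]),
                         total, frac))
    pd.DataFrame(cov_rows, columns=[
        "percentile", "threshold", "n_signals", "covered_bp", "genome_fraction",
    ]).to_csv(out / "coverage_summary.tsv", sep="\t", index=False)
    if result.overlaps is not None:
        result.overlaps.to_csv(out / "annotation_overlap.tsv", sep="\t",
                               index=False)

    manifest = {
        "comparison": result.label,
        "seed": config.seed,
        "parameters": {
            "window_size": config.window_size, "step": config.step,
            "percentiles": list(config.percentiles),
            "qc": vars(config.qc),
        },
        "inputs": {
            label: {"ped": _sha256(Path(ped)), "map": _sha256(Path(map_))}
            for label, ped, map_ in config.inputs
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_annotations(config: RunConfig) -> pd.DataFrame | None:
    frames = []
    for path, source in ((config.gene_bed, "gene"), (config.cnv_bed, "cnv")):
        if path is None:
            continue
        if not Path(path).exists():
            raise FileNotFoundError(f"annotation file not found: {path}")
        frames.append(read_bed_intervals(path, source=source))
    return pd.concat(frames, ignore_index=True) if frames else None


def _stack(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    return GenotypeDataset(
        a.sample_ids + b.sample_ids, f"{a.population}+{b.population}",
        a.markers, np.vstack([a.dosages, b.dosages]), _validated=True,
    )


# ---------------------------------------------------------------------------
# multi-population panel
# ---------------------------------------------------------------------------

def run_comparisons(
    datasets: list[GenotypeDataset],
    window_size: int = 50,
    step: int = 1,
    percentiles: tuple[float, ...] = (99.9, 99.99),
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run every unordered pairwise comparison of a QC'd panel.

    Returns the concatenated signal table (lowest percentile, i.e. the
    inclusive threshold) with a ``shared_with`` column marking signals whose
    interval overlaps a signal from another comparison.  A failed pair is
    reported in the table's attrs and does not stop the others.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two populations")
    frames, failures = [], {}
    for a, b in combinations(datasets, 2):
        try:
            res = run_comparison(a, b, window_size, step, percentiles,
                                 annotations, compute_decay=False)
        except Exception as exc:  # keep remaining pairs running
            failures[f"{a.population}/{b.population}"] = str(exc)
            warnings.warn(f"comparison {a.population}/{b.population} failed: {exc}")
            continue
        frames.append(regions_to_frame(res.regions[min(percentiles)]))
    combined = (pd.concat(frames, ignore_index=True) if frames
                else regions_to_frame([]))
    combined["shared_with"] = ""
    for i in combined.index:
        hits = []
        for j in combined.index:
            if (combined.at[j, "comparison"] != combined.at[i, "comparison"]
                    and combined.at[j, "chromosome"] == combined.at[i, "chromosome"]
                    and combined.at[j, "start_bp"] <= combined.at[i, "end_bp"]
                    and combined.at[i, "start_bp"] <= combined.at[j, "end_bp"]):
                hits.append(combined.at[j, "comparison"])
        combined.at[i, "shared_with"] = ";".join(sorted(set(hits)))
    combined.attrs["failures"] = failures
    return combined
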