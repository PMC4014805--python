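"""Signal calling on a standardized scan track, sweep-to-population
assignment, and interval overlap against gene/CNV annotations.

A window is flagged when its standardized score meets the percentile
threshold; flagged windows whose SNP-index ranges overlap or abut merge
into one signal region, whose boundaries are the midpoints of its first and
last windows.  A region is then assigned to the population with the higher
regional mean pairwise r^2 — under a sweep, the selected population carries
the collapsed haplotypes and hence the elevated LD.

All genomic coordinates here are 1-based and inclusive at both ends; BED
export converts back to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset
from .genotype_io import write_bed_intervals
from .ld_stats import mean_pairwise_r2
from .varld_core import VarLDTrack

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AnnotationInterval:
    """A named genomic interval (gene or CNV), 1-based inclusive."""

    chromosome: str
    start_bp: int
    end_bp: int
    name: str
    source: str = "gene"  # {"gene", "cnv"}

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("interval start_bp must be <= end_bp")


def intervals_to_frame(intervals: list[AnnotationInterval]) -> pd.DataFrame:
    """Interval table in the layout of
    :func:`ldcontrast.genotype_io.read_bed_intervals`."""
    return pd.DataFrame(
        [(i.chromosome, i.start_bp, i.end_bp, i.name, i.source)
         for i in intervals],
        columns=["chromosome", "start_bp", "end_bp", "name", "source"],
    )


@dataclass
class SignalRegion:
    """A merged run of above-threshold windows."""

    comparison_label: str
    chromosome: str
    start_bp: int
    end_bp: int
    peak_std_score: float
    n_windows: int
    first_window_index: int
    last_window_index: int
    assigned_population: str | None = None
    assignment_margin: float = float("nan")
    assignment_tie: bool = False

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("region start_bp must be <= end_bp")
        if self.n_windows < 1:
            raise ValueError("region must contain at least one window")


def regions_to_frame(regions: list[SignalRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "comparison": r.comparison_label,
        "chromosome": r.chromosome,
        "start_bp": r.start_bp,
        "end_bp": r.end_bp,
        "peak_std_score": r.peak_std_score,
        "n_windows": r.n_windows,
        "assigned_population": r.assigned_population or UNASSIGNED,
        "assignment_margin": r.assignment_margin,
    } for r in regions])


def regions_to_bed(regions: list[SignalRegion], path) -> None:
    df = regions_to_frame(regions)
    if df.empty:
        open(path, "w").close()
        return
    df = df.assign(name=[
        f"{r.comparison_label}:{r.assigned_population or UNASSIGNED}"
        for r in regions
    ])
    write_bed_intervals(df[["chromosome", "start_bp", "end_bp", "name"]], path)


# ---------------------------------------------------------------------------
# thresholding and calling
# ---------------------------------------------------------------------------

def percentile_threshold(track: VarLDTrack, percentile: float) -> float:
    """Empirical quantile of the standardized scores (linear interpolation
    between order statistics)."""
    if len(track.scores) == 0:
        raise ValueError("empty track")
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must be in (0, 100]")
    if not track.is_standardized:
        raise ValueError("track must be standardized first")
    return float(np.percentile(track.scores["std_score"].to_numpy(), percentile))


def call_signals(track: VarLDTrack, threshold: float) -> list[SignalRegion]:
    """Flag windows with std_score >= threshold and merge flagged windows on
    the same chromosome whose SNP-index ranges overlap or abut.

    Region boundaries are the mid-bp of the first and last constituent
    windows; regions are sorted by (chromosome, start_bp).
    """
    if not track.is_standardized:
        raise ValueError("track must be standardized first")
    df = track.scores
    flagged = df[df["std_score"] >= threshold]
    regions: list[SignalRegion] = []
    w = track.window_size
    for chrom, grp in flagged.groupby("chromosome", sort=False):
        grp = grp.sort_values("first_snp_index")
        run: list[pd.Series] = []
        for _, row in grp.iterrows():
            if run and row["first_snp_index"] > run[-1]["first_snp_index"] + w:
                regions.append(_make_region(track, chrom, run))
                run = []
            run.append(row)
        if run:
            regions.append(_make_region(track, chrom, run))
    regions.sort(key=lambda r: (r.chromosome, r.start_bp))
    return regions


def _make_region(track: VarLDTrack, chrom: str, run: list[pd.Series]) -> SignalRegion:
    return SignalRegion(
        comparison_label=track.comparison_label,
        chromosome=str(chrom),
        start_bp=int(run[0]["mid_bp"]),
        end_bp=int(run[-1]["mid_bp"]),
        peak_std_score=float(max(r["std_score"] for r in run)),
        n_windows=len(run),
        first_window_index=int(run[0]["first_snp_index"]),
        last_window_index=int(run[-1]["first_snp_index"]),
    )


# ---------------------------------------------------------------------------
# breed/population assignment
# ---------------------------------------------------------------------------

def assign_population(
    region: SignalRegion, a: GenotypeDataset, b: GenotypeDataset
) -> tuple[str, float]:
    """Assign a signal region to the population with the higher regional
    mean pairwise r^2; returns (label, margin).

    With fewer than two SNPs in the region the sentinel ``unassigned`` is
    returned; an exact tie goes to the first population with
    ``assignment_tie`` set on the region.
    """
    means = []
    for ds in (a, b):
        sel = (
            (ds.markers["chromosome"] == region.chromosome)
            & (ds.markers["position_bp"] >= region.start_bp)
            & (ds.markers["position_bp"] <= region.end_bp)
        ).to_numpy()
        if sel.sum() < 2:
            region.assigned_population = UNASSIGNED
            region.assignment_margin = float("nan")
            return UNASSIGNED, float("nan")
        means.append(mean_pairwise_r2(ds.dosages[:, sel]))
    margin = float(abs(means[0] - means[1]))
    if means[0] == means[1]:
        warnings.warn(
            f"regional LD tie in {region.comparison_label} "
            f"{region.chromosome}:{region.start_bp}-{region.end_bp}; "
            f"assigned to {a.population} by convention"
        )
        region.assignment_tie = True
        label = a.population
    else:
        label = a.population if means[0] > means[1] else b.population
    region.assigned_population = label
    region.assignment_margin = margin
    return label, margin


# ---------------------------------------------------------------------------
# annotation overlap and coverage
# ---------------------------------------------------------------------------

def overlap_annotations(
    regions: list[SignalRegion], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Report every (region, annotation) pair sharing >= 1 bp.

    ``annotations`` is the interval table produced by
    :func:`ldcontrast.genotype_io.read_bed_intervals` (1-based inclusive).
    The result carries the overlap length in bp per pair.
    """
    if isinstance(annotations, list):
        annotations = intervals_to_frame(annotations)
    rows = []
    for r in regions:
        ann = annotations[annotations["chromosome"] == r.chromosome]
        for row in ann.itertuples(index=False):
            lo = max(r.start_bp, row.start_bp)
            hi = min(r.end_bp, row.end_bp)
            if lo <= hi:
                rows.append({
                    "comparison": r.comparison_label,
                    "chromosome": r.chromosome,
                    "region_start_bp": r.start_bp,
                    "region_end_bp": r.end_bp,
                    "name": row.name,
                    "source": row.source,
                    "annotation_start_bp": row.start_bp,
                    "annotation_end_bp": row.end_bp,
                    "overlap_bp": hi - lo + 1,
                })
    return pd.DataFrame(rows, columns=[
        "comparison", "chromosome", "region_start_bp", "region_end_bp",
        "name", "source", "annotation_start_bp", "annotation_end_bp",
        "overlap_bp",
    ])


def coverage_summary(
    regions: list[SignalRegion], chromosome_lengths: dict[str, int] | pd.Series
) -> tuple[int, float]:
    """Total bp covered by the union of the regions and the fraction of the
    genome (sum of chromosome lengths) they represent."""
    lengths = dict(chromosome_lengths)
    genome = sum(lengths.values())
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        if r.chromosome not in lengths:
            raise ValueError(f"region on unknown chromosome {r.chromosome}")
        if r.end_bp > lengths[r.chromosome] or r.start_bp < 1:
            raise ValueError(
                f"region {r.chromosome}:{r.start_bp}-{r.end_bp} exceeds "
                f"chromosome length {lengths[r.chromosome]}"
            )
        by_chrom.setdefault(r.chromosome, []).append((r.start_bp, r.end_bp))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    fraction = total / genome if genome else 0.0
    return total, fraction
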