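"""Reading and writing genotype data.

Two on-disk dialects are supported:

* PLINK text PED/MAP — the reference interchange format.  PED rows carry six
  leading columns (family, individual, father, mother, sex, phenotype)
  followed by two allele characters per marker; ``0`` is the missing allele.
* An internal dosage table — a TSV with a header of marker ids and one row
  per sample, paired with a marker-map TSV.

Alleles are inferred from the observed characters; the dosage counts copies
of the lexicographically later allele (``allele_b``), which is deterministic
without an external reference.  When a marker shows a single allele in the
data, the unobserved partner is synthesized as ``z`` (which sorts after every
base code), so a monomorphic column always reads as dosage 0; PED text does
not record unobserved alleles, so round-trip identity of dosages is
guaranteed for markers where both alleles are observed.

Annotation intervals (genes, CNV regions) are ingested from BED 3+ files;
BED's 0-based half-open coordinates are converted to the package's 1-based
inclusive convention on read and back on write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import DatasetError, GenotypeDataset, MARKER_COLUMNS


class FormatError(ValueError):
    """Malformed input file (ragged rows, dimension mismatch, bad field)."""


MISSING_ALLELE = "0"


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK MAP file (chrom, marker_id, [cM,] bp)."""
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, mid, _cm, bp = fields
            elif len(fields) == 3:
                chrom, mid, bp = fields
            else:
                raise FormatError(f"{map_path}: line {ln}: expected 3 or 4 fields")
            rows.append((mid, chrom, int(bp)))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])


def read_ped_map(ped_path, map_path, population_label: str) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    ``0 0`` genotypes become missing; markers are sorted by
    (chromosome, position) on return.

    Raises
    ------
    FormatError
        On ragged PED rows or a marker-count mismatch with the MAP file.
    DatasetError
        If a marker shows more than two distinct alleles.
    """
    mp = read_map(map_path)
    m = len(mp)
    sample_ids: list[str] = []
    allele1: list[list[str]] = []
    allele2: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields "
                    f"({m} markers), found {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele1.append(fields[6::2])
            allele2.append(fields[7::2])
    n = len(sample_ids)
    a1 = np.array(allele1, dtype="U8").reshape(n, m) if n else np.empty((0, m), "U8")
    a2 = np.array(allele2, dtype="U8").reshape(n, m) if n else np.empty((0, m), "U8")

    dosages = np.full((n, m), np.nan)
    rec_a, rec_b = [], []
    for j in range(m):
        obs = set(a1[:, j]) | set(a2[:, j])
        obs.discard(MISSING_ALLELE)
        if len(obs) > 2:
            raise DatasetError(
                f"marker {mp['marker_id'].iloc[j]}: more than 2 alleles {sorted(obs)}"
            )
        if len(obs) == 2:
            aa, ab = sorted(obs)
        elif len(obs) == 1:
            # single observed allele: the unobserved partner is synthesized
            # as 'z' (sorts after any base code) so the column reads as
            # dosage 0 — "count of the absent allele".  Monomorphic columns
            # are inherently ambiguous in PED text; documented limitation.
            only = obs.pop()
            aa, ab = only, ("z" if only != "z" else "y")
            aa, ab = sorted([aa, ab])
        else:  # no calls at all
            aa, ab = "y", "z"
        rec_a.append(aa)
        rec_b.append(ab)
        if n:
            miss = (a1[:, j] == MISSING_ALLELE) | (a2[:, j] == MISSING_ALLELE)
            d = (a1[:, j] == ab).astype(float) + (a2[:, j] == ab).astype(float)
            d[miss] = np.nan
            dosages[:, j] = d

    markers = mp.copy()
    markers["allele_a"] = rec_a
    markers["allele_b"] = rec_b
    markers = markers[MARKER_COLUMNS]
    ds = GenotypeDataset(sample_ids, population_label, markers, dosages)
    return ds.sort_markers()


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset as a PLINK text PED/MAP pair, re-readable by
    :func:`read_ped_map` with dosages preserved."""
    with open(map_path, "w") as fh:
        for row in dataset.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")
    aa = dataset.markers["allele_a"].to_numpy()
    ab = dataset.markers["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            d = dataset.dosages[i]
            g = np.empty(2 * len(d), dtype="U8")
            g[0::2] = np.where(np.isnan(d), MISSING_ALLELE, np.where(d >= 1, ab, aa))
            g[1::2] = np.where(np.isnan(d), MISSING_ALLELE, np.where(d == 2, ab, aa))
            fh.write(
                "\t".join([dataset.population, sid, "0", "0", "0", "-9", *g]) + "\n"
            )


# ---------------------------------------------------------------------------
# internal dosage table
# ---------------------------------------------------------------------------

def write_dosage_table(dataset: GenotypeDataset, dosage_path, marker_path) -> None:
    """Write the internal TSV dialect: a dosage table headed by marker ids
    plus a companion marker-map TSV."""
    df = pd.DataFrame(
        dataset.dosages, index=pd.Index(dataset.sample_ids, name="sample_id"),
        columns=dataset.markers["marker_id"],
    )
    df.to_csv(dosage_path, sep="\t", na_rep="NA")
    dataset.markers.to_csv(marker_path, sep="\t", index=False)


def read_dosage_table(dosage_path, marker_path, population_label: str) -> GenotypeDataset:
    """Read the internal TSV dialect written by :func:`write_dosage_table`."""
    markers = pd.read_csv(marker_path, sep="\t", dtype={"chromosome": str})
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA"])
    if list(df.columns) != list(markers["marker_id"]):
        raise FormatError("dosage header does not match the marker map")
    return GenotypeDataset(
        [str(s) for s in df.index], population_label, markers[MARKER_COLUMNS],
        df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# marker intersection / allele harmonization
# ---------------------------------------------------------------------------

def intersect_common_snps(
    a: GenotypeDataset, b: GenotypeDataset
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Restrict two datasets to their shared markers, harmonizing alleles.

    Markers match on (chromosome, position).  If a marker's alleles are
    swapped between the datasets, dosages in ``b`` are recoded as ``2 - d``;
    markers whose allele sets differ beyond a swap are dropped.  Strand-
    ambiguous A/T and C/G swaps are treated as plain swaps (single-platform
    convention; documented limitation).

    Raises
    ------
    DatasetError
        If no markers are shared.
    """
    key_a = list(zip(a.markers["chromosome"], a.markers["position_bp"]))
    key_b = list(zip(b.markers["chromosome"], b.markers["position_bp"]))
    pos_b = {k: j for j, k in enumerate(key_b)}

    idx_a, idx_b, flip = [], [], []
    for i, k in enumerate(key_a):
        j = pos_b.get(k)
        if j is None:
            continue
        aa, ab_ = a.markers["allele_a"].iloc[i], a.markers["allele_b"].iloc[i]
        ba, bb = b.markers["allele_a"].iloc[j], b.markers["allele_b"].iloc[j]
        if (aa, ab_) == (ba, bb):
            idx_a.append(i); idx_b.append(j); flip.append(False)
        elif (aa, ab_) == (bb, ba):
            idx_a.append(i); idx_b.append(j); flip.append(True)
        # otherwise: incompatible allele sets -> drop
    if not idx_a:
        raise DatasetError("no common markers between the two datasets")

    out_a = a.select_markers(np.asarray(idx_a, dtype=int))
    out_b = b.select_markers(np.asarray(idx_b, dtype=int))
    flip = np.asarray(flip)
    if flip.any():
        d = out_b.dosages.copy()
        d[:, flip] = 2.0 - d[:, flip]
        mk = out_b.markers.copy()
        mk.loc[flip, ["allele_a", "allele_b"]] = mk.loc[
            flip, ["allele_b", "allele_a"]
        ].to_numpy()
        out_b = GenotypeDataset(out_b.sample_ids, out_b.population, mk, d,
                                _validated=True)
    # align marker ids so both outputs carry identical maps
    mk_b = out_b.markers.copy()
    mk_b["marker_id"] = out_a.markers["marker_id"].to_numpy()
    out_b = GenotypeDataset(out_b.sample_ids, out_b.population, mk_b,
                            out_b.dosages, _validated=True)
    return out_a, out_b


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed_intervals(path, source: str = "gene") -> pd.DataFrame:
    """Read a BED 3+/4-column file into a 1-based inclusive interval table
    with columns (chromosome, start_bp, end_bp, name, source)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(f"{path}: line {ln}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 else f"{source}_{ln}"
            start0, end0 = int(f[1]), int(f[2])
            if end0 <= start0:
                raise FormatError(f"{path}: line {ln}: empty/negative interval")
            rows.append((str(f[0]), start0 + 1, end0, name, source))
    return pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "name", "source"]
    )


def write_bed_intervals(table: pd.DataFrame, path) -> None:
    """Write a 1-based inclusive interval table as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start_bp - 1}\t{row.end_bp}\t{row.name}\n"
            )
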