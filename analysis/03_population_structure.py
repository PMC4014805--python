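#!/usr/bin/env python
"""Population structure: genomic kinship -> squared distances -> classical
MDS of the combined panel over the shared markers.

Prints the variance explained by the first two dimensions and writes the
coordinates (and a scatter plot) — the two populations should separate
cleanly on dimension 1.

Outputs under results/structure/: mds_coordinates.tsv, mds.png.
"""

import argparse
from pathlib import Path

import numpy as np

from ldcontrast import (classical_mds, ibs_kinship, intersect_common_snps,
                        kinship_to_sq_distance, read_dosage_table)
from ldcontrast.dataset import GenotypeDataset
from ldcontrast.plots import plot_mds


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/qc"))
    ap.add_argument("--outdir", type=Path, default=Path("results/structure"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    pops = []
    for pop in ("POP1", "POP2"):
        pops.append(read_dosage_table(args.indir / f"{pop}.dosage.tsv",
                                      args.indir / f"{pop}.markers.tsv", pop))
    a, b = intersect_common_snps(*pops)
    combined = GenotypeDataset(
        a.sample_ids + b.sample_ids, "panel", a.markers,
        np.vstack([a.dosages, b.dosages]), _validated=True)
    labels = [a.population] * a.n_samples + [b.population] * b.n_samples

    mds = classical_mds(kinship_to_sq_distance(ibs_kinship(combined)), k=2)
    mds.to_frame(combined.sample_ids, labels).to_csv(
        args.outdir / "mds_coordinates.tsv", sep="\t", index=False)
    plot_mds(mds, labels, args.outdir / "mds.png")
    print(f"dim 1 explains {100 * mds.explained_fraction[0]:.1f}% of the "
          f"kinship variance, dim 2 {100 * mds.explained_fraction[1]:.1f}%")


if __name__ == "__main__":
    main()
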