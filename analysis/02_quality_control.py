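#!/usr/bin/env python
"""Per-population QC: call rates, MAF, Hardy-Weinberg, relatedness pruning.

Reads the PED/MAP cohorts written by 01_simulate_cohorts.py, applies the
standard thresholds (MAF >= 5%, call rate >= 90% per SNP and per sample,
HWE p > 1e-6, kinship > 0.8 pruning) separately per population, and writes
the cleaned data plus QC reports.

Outputs under results/qc/: <POP>.dosage.tsv/.markers.tsv, qc_report_<POP>.tsv.
"""

import argparse
from pathlib import Path

from ldcontrast import QCConfig, apply_qc, read_ped_map, write_dosage_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/qc"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = QCConfig()
    for pop in ("POP1", "POP2"):
        ds = read_ped_map(args.indir / f"{pop}.ped", args.indir / f"{pop}.map", pop)
        clean, report = apply_qc(ds, cfg)
        write_dosage_table(clean, args.outdir / f"{pop}.dosage.tsv",
                           args.outdir / f"{pop}.markers.tsv")
        report.to_tsv(args.outdir / f"qc_report_{pop}.tsv")
        print(f"{pop}: samples {report.n_samples_in} -> {report.n_samples_out}, "
              f"SNPs {report.n_snps_in} -> {report.n_snps_out}; "
              f"removed per filter: {report.removed_by_filter}")


if __name__ == "__main__":
    main()
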