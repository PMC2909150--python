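#!/usr/bin/env python
"""Genotype QC on the simulated cohort: within-plex individual call-rate
masking (70%), SNP call-rate filter (95%, among attempted samples) and the
Hardy-Weinberg exact-test filter (p > 0.01 retained).

Reads results/cohort/, writes the QC'd matrix and audit report to
results/qc/.
"""

import argparse
from pathlib import Path

from snpset_generalist import io
from snpset_generalist.qc import QcConfig, run_qc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/qc"))
    args = ap.parse_args()

    gm = io.read_genotypes(args.cohort / "genotypes", "pedmap",
                           panel=args.cohort / "panel.tsv")
    kept, report = run_qc(gm, QcConfig())
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_genotypes(kept, args.out / "genotypes_qc", "pedmap")
    io.write_panel(kept.snps, args.out / "panel_qc.tsv")
    report.to_json(args.out / "qc_report.json")

    print(f"input:  {gm.n_individuals} individuals x {gm.n_snps} SNPs")
    print(f"kept:   {kept.n_individuals} individuals x {kept.n_snps} SNPs")
    print("per-plex individual removals:",
          dict(sorted(report.plex_removal_counts.items())))
    print(f"individuals removed outright: {len(report.removed_individuals)}")
    print(f"SNPs removed: {report.removed_snps or 'none'}")
    print(f"report -> {args.out / 'qc_report.json'}")


if __name__ == "__main__":
    main()
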