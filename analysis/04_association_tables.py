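#!/usr/bin/env python
"""Association of the SNP sets and top single SNPs with every measure.

Measures are sex/age-residualized and standardized first.  Each predictor x
measure cell carries the pairwise-complete Pearson r, its N, the one-tailed
p and nominal/Bonferroni (m=5) flags; an r_p row gives each measure's
phenotypic correlation with the focal maths composite.  Writes
results/association/association_table.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from snpset_generalist import io
from snpset_generalist.assoc import AnalysisPlan, association_table, format_report
from snpset_generalist.pheno import prepare_measures
from snpset_generalist.snpset import additive_matrix


def load_inputs(qc_dir: Path, scores_path: Path, cohort_dir: Path):
    gm = io.read_genotypes(qc_dir / "genotypes_qc", "pedmap",
                           panel=qc_dir / "panel_qc.tsv")
    scores = pd.read_csv(scores_path, sep="\t", index_col="individual_id")
    table = io.read_phenotypes(cohort_dir / "phenotypes.tsv")
    return gm, scores, table


def build_predictors(gm, scores, n_single=3):
    codes = additive_matrix(gm)
    predictors = {gm.snp_ids[j]: pd.Series(codes[:, j],
                                           index=gm.individual_ids,
                                           name=gm.snp_ids[j])
                  for j in range(n_single)}
    for name, grp in scores.groupby("snp_set", sort=False):
        predictors[name] = grp["score"]
    return predictors


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--qc", type=Path, default=Path("results/qc"))
    ap.add_argument("--scores", type=Path,
                    default=Path("results/scores/scores.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/association"))
    args = ap.parse_args()

    gm, scores, table = load_inputs(args.qc, args.scores, args.cohort)
    adjusted = prepare_measures(table)
    plan = AnalysisPlan(predictors=build_predictors(gm, scores),
                        measures=list(adjusted.measures),
                        m_tests_per_measure=5, focal_measure="math10")
    out_df = association_table(plan, adjusted)
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_association_report(out_df, args.out / "association_table.csv")
    io.write_phenotypes(adjusted, args.out / "adjusted_phenotypes.tsv")

    show = out_df[out_df.measure.isin(["math10", "math9", "g10",
                                       "reading10", "motivation12"])]
    print(format_report(show).to_string(index=False))
    sets = out_df[out_df.predictor.str.endswith("SNP set")
                  & (out_df.measure == "math10")]
    print("\nfocal maths composite:",
          ", ".join(f"{r.predictor} r={r.r:.3f} (N={r.N})"
                    for r in sets.itertuples()))
    print(f"full table -> {args.out / 'association_table.csv'}")


if __name__ == "__main__":
    main()
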