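"""Association of SNP predictors with quantitative measures.

The test statistic is the Pearson product-moment correlation on
pairwise-complete cases.  Because additive coding already orients every
predictor toward higher trait values, inference is one-tailed in the positive
direction: p is the upper tail of t = r * sqrt((N-2)/(1-r^2)) on N-2 degrees
of freedom, so a wrong-direction correlation yields p > 0.5.  Significance is
flagged nominally (p < 0.05) and after Bonferroni correction for the m tests
run per measure (p < 0.05/m; m = 5 here: two SNP sets and three single SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import DegenerateInputError
from .io import PhenotypeTable
from . import pheno

DEFAULT_M_TESTS = 5


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    measure: str
    r: float
    N: int
    p_one_tailed: float
    nominal: bool
    bonferroni: bool


@dataclass
class AnalysisPlan:
    """Which predictors are tested against which measures.

    ``predictors`` maps label -> per-individual score Series (SNP-set scores
    or single-SNP additive codes).  ``m_tests_per_measure`` is the Bonferroni
    family size.  ``controls`` optionally maps an analysis label to the list
    of measures to regress out of the focal measure first.
    """

    predictors: dict[str, pd.Series]
    measures: list[str]
    m_tests_per_measure: int = DEFAULT_M_TESTS
    focal_measure: str | None = None
    controls: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m_tests_per_measure < 1:
            raise ValueError("m_tests_per_measure must be >= 1")


def pearson_r(x: pd.Series, y: pd.Series) -> tuple[float, int]:
    """Pearson correlation on pairwise-complete cases; returns (r, N)."""
    x, y = x.align(y, join="inner")
    complete = x.notna() & y.notna()
    n = int(complete.sum())
    if n < 3:
        raise DegenerateInputError(f"only {n} complete pairs")
    xv = x[complete].to_numpy(float)
    yv = y[complete].to_numpy(float)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise DegenerateInputError("constant input on complete pairs")
    return float(xc @ yc / denom), n


def one_tailed_p(r: float, N: int) -> float:
    """Upper-tail p-value for a positive-direction correlation test."""
    if N < 3:
        raise DegenerateInputError(f"N={N} < 3")
    if abs(r) >= 1:
        return 0.0 if r > 0 else 1.0
    t = r * np.sqrt((N - 2) / (1.0 - r * r))
    return float(t_dist.sf(t, N - 2))


def significance_flags(p: float, m: int = DEFAULT_M_TESTS) -> tuple[bool, bool]:
    """(nominal, Bonferroni) flags at alpha 0.05 and 0.05/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < 0.05, p < 0.05 / m


def associate(predictor: pd.Series, measure: pd.Series,
              m: int = DEFAULT_M_TESTS,
              predictor_label: str | None = None,
              measure_label: str | None = None) -> AssociationResult:
    """One table cell: r, N, one-tailed p and significance flags."""
    r, n = pearson_r(predictor, measure)
    p = one_tailed_p(r, n)
    nominal, bonf = significance_flags(p, m)
    return AssociationResult(
        predictor=predictor_label or str(predictor.name),
        measure=measure_label or str(measure.name),
        r=r, N=n, p_one_tailed=p, nominal=nominal, bonferroni=bonf)


def regress_out_and_associate(predictor: pd.Series, measure: pd.Series,
                              controls, m: int = DEFAULT_M_TESTS,
                              partial: bool = False,
                              predictor_label: str | None = None,
                              measure_label: str | None = None
                              ) -> AssociationResult:
    """Associate after regressing the control measures out of the phenotype.

    By default only the phenotype is residualized (specificity analysis);
    ``partial=True`` residualizes the predictor too, giving the full partial
    correlation.  N shrinks to the joint-complete sample.
    """
    adj = pheno.residualize(measure, controls, restandardize=True)
    pred = predictor
    if partial:
        pred = pheno.residualize(predictor, controls, restandardize=True)
    label = measure_label or f"{measure.name}|{'+'.join(c.name for c in controls)}"
    return associate(pred, adj, m, predictor_label=predictor_label,
                     measure_label=label)


def association_table(plan: AnalysisPlan, table: PhenotypeTable) -> pd.DataFrame:
    """Association report: one row per predictor x measure plus, when a focal
    measure is named, a phenotypic-correlation row ``r_p`` giving each
    measure's two-tailed-context correlation with the focal composite
    (r and N only).  Deterministic given its inputs."""
    rows = []
    for plabel, scores in plan.predictors.items():
        for mlabel in plan.measures:
            res = associate(scores, table.measure(mlabel),
                            plan.m_tests_per_measure,
                            predictor_label=plabel, measure_label=mlabel)
            rows.append({"predictor": res.predictor, "measure": res.measure,
                         "r": res.r, "N": res.N,
                         "p_one_tailed": res.p_one_tailed,
                         "nominal_sig": res.nominal,
                         "bonferroni_sig": res.bonferroni})
    if plan.focal_measure is not None:
        focal = table.measure(plan.focal_measure)
        for mlabel in plan.measures:
            if mlabel == plan.focal_measure:
                rows.append({"predictor": "r_p", "measure": mlabel,
                             "r": np.nan, "N": np.nan,
                             "p_one_tailed": np.nan,
                             "nominal_sig": None, "bonferroni_sig": None})
                continue
            r, n = pearson_r(focal, table.measure(mlabel))
            rows.append({"predictor": "r_p", "measure": mlabel, "r": r, "N": n,
                         "p_one_tailed": np.nan,
                         "nominal_sig": None, "bonferroni_sig": None})
    return pd.DataFrame(rows)


def format_report(df: pd.DataFrame) -> pd.DataFrame:
    """Report formatting: r to 3 decimals, p in scientific notation (3 s.f.)."""
    out = df.copy()
    out["r"] = out["r"].map(lambda v: f"{v:.3f}" if pd.notna(v) else "NA")
    out["p_one_tailed"] = out["p_one_tailed"].map(
        lambda v: f"{v:.2E}" if pd.notna(v) else "NA")
    return out
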