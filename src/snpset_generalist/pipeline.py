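"""One-command orchestration: simulate (or load) -> QC -> score -> prepare
measures -> associate -> regress-out -> power annex -> report bundle.

The whole analysis is declared in one :class:`RunConfig` (loadable from
YAML); `run_full_analysis` writes, under the output directory:

* ``qc_report.json`` — every QC removal with reasons,
* ``scores.tsv`` — per-individual SNP-set scores,
* ``adjusted_phenotypes.tsv`` — sex/age-residualized standardized measures,
* ``association_table.csv`` — one row per predictor x measure (r, N,
  one-tailed p, nominal and Bonferroni flags) plus the phenotypic-correlation
  ``r_p`` rows,
* ``regress_out.csv`` — focal-measure associations with control measures
  regressed out,
* ``power.csv`` — detectable effect sizes for the configured designs,
* ``run_log.json`` — seed, config hash and stage record.

Deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assoc, io, pheno, power as power_mod, qc, snpset
from .errors import ConfigError
from .simcohort import SimulationSpec, simulate_cohort, teds_like_spec


@dataclass
class RunConfig:
    """Declarative description of a full analysis run.

    Exactly one of ``simulation`` (generate a cohort) or ``genotype_path`` +
    ``phenotype_path`` (+ ``panel_path``) must be given.
    """

    out_dir: str = "results/run"
    simulation: SimulationSpec | None = None
    genotype_path: str | None = None
    genotype_format: str = "pedmap"
    panel_path: str | None = None
    phenotype_path: str | None = None
    qc_config: qc.QcConfig = field(default_factory=qc.QcConfig)
    snpset_sizes: tuple[int, int] = (10, 43)  # replicated + full panel
    max_missing_full_set: int = 3
    n_single_snps: int = 3
    m_tests_per_measure: int = assoc.DEFAULT_M_TESTS
    focal_measure: str | None = None
    control_sets: dict[str, list[str]] = field(default_factory=dict)
    power_designs: tuple[tuple[int, float], ...] = (
        (2112, 0.067), (1431, 0.084), (3891, 0.05))
    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.genotype_path is not None
        if has_sim == has_paths:
            raise ConfigError(
                "exactly one of a simulation spec or input paths is required")


def default_config(out_dir: str = "results/run", seed: int = 0) -> RunConfig:
    """The packaged study-like run: simulated cohort, focal maths composite,
    regress-out controls mirroring the specificity analyses."""
    spec = teds_like_spec(seed=seed)
    return RunConfig(
        out_dir=out_dir, simulation=spec, focal_measure="math10",
        control_sets={
            "g_controlled": ["g10"],
            "reading_controlled": ["reading10"],
            "g_and_reading_controlled": ["g10", "reading10"],
        },
        seed=seed)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML.

    The ``simulation`` block maps onto :class:`SimulationSpec` (with
    ``traits`` as a list of label/rho/phenotypic_noise_link/age_mean
    mappings and a ``missingness`` sub-block); ``qc`` maps onto
    :class:`QcConfig`; remaining keys map onto RunConfig fields.
    """
    import yaml

    from .simcohort import MissingnessSpec, TraitSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = dict(raw)
    if "simulation" in kwargs and kwargs["simulation"] is not None:
        sim = dict(kwargs["simulation"])
        traits = [TraitSpec(**t) for t in sim.pop("traits", [])]
        miss = MissingnessSpec(**sim.pop("missingness", {}))
        kwargs["simulation"] = SimulationSpec(trait_specs=traits,
                                              missingness=miss, **sim)
    if "qc" in kwargs:
        kwargs["qc_config"] = qc.QcConfig(**kwargs.pop("qc"))
    for key in ("snpset_sizes", "power_designs"):
        if key in kwargs:
            kwargs[key] = tuple(tuple(x) if isinstance(x, list) else x
                                for x in kwargs[key])
            if key == "snpset_sizes":
                kwargs[key] = tuple(int(v) for v in kwargs[key])
    return RunConfig(**kwargs)


def _config_hash(cfg: RunConfig) -> str:
    text = repr(cfg).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def run_full_analysis(cfg: RunConfig) -> dict[str, object]:
    """Execute every stage and write the report bundle; returns the in-memory
    artifacts keyed by name."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, object] = {"seed": cfg.seed, "config_hash": _config_hash(cfg),
                              "stages": []}

    def stage(name):
        log["stages"].append(name)

    # --- inputs -----------------------------------------------------------
    if cfg.simulation is not None:
        stage("simulate")
        gm, table, truth = simulate_cohort(cfg.simulation)
        truth.to_json(out / "truth.json")
    else:
        stage("load")
        gm = io.read_genotypes(cfg.genotype_path, cfg.genotype_format,
                               panel=cfg.panel_path)
        table = io.read_phenotypes(cfg.phenotype_path)
        truth = None

    # --- QC ---------------------------------------------------------------
    stage("qc")
    gm, report = qc.run_qc(gm, cfg.qc_config)
    report.to_json(out / "qc_report.json")

    # --- SNP-set scores ---------------------------------------------------
    stage("score")
    k_small, k_full = cfg.snpset_sizes
    k_small = min(k_small, gm.n_snps)
    defs = [snpset.SnpSetDefinition(
        f"{k_small}-SNP set", tuple(gm.snp_ids[:k_small]),
        policy=snpset.COMPLETE_ONLY)]
    if gm.n_snps > k_small:
        defs.append(snpset.SnpSetDefinition(
            f"{gm.n_snps}-SNP set", tuple(gm.snp_ids),
            policy=snpset.MEAN_SUBSTITUTE,
            max_missing=min(cfg.max_missing_full_set, gm.n_snps - 1)))
    scores: dict[str, pd.Series] = {}
    score_frames = []
    for d in defs:
        sc = snpset.build_snpset_scores(gm, d)
        scores[d.name] = sc["score"]
        sc = sc.copy()
        sc.insert(0, "snp_set", d.name)
        score_frames.append(sc)
    pd.concat(score_frames).to_csv(out / "scores.tsv", sep="\t", na_rep="NA")

    codes = snpset.additive_matrix(gm)
    single = {gm.snp_ids[j]: pd.Series(codes[:, j], index=gm.individual_ids,
                                       name=gm.snp_ids[j])
              for j in range(min(cfg.n_single_snps, gm.n_snps))}

    # --- phenotype preparation -------------------------------------------
    stage("prepare")
    adjusted = pheno.prepare_measures(table)
    io.write_phenotypes(adjusted, out / "adjusted_phenotypes.tsv")

    # --- associations -----------------------------------------------------
    stage("associate")
    predictors = {**single, **scores}
    focal = cfg.focal_measure or adjusted.measures[0]
    plan = assoc.AnalysisPlan(predictors=predictors,
                              measures=list(adjusted.measures),
                              m_tests_per_measure=cfg.m_tests_per_measure,
                              focal_measure=focal)
    table_df = assoc.association_table(plan, adjusted)
    io.write_association_report(table_df, out / "association_table.csv")

    # --- regress-out specificity -----------------------------------------
    stage("regress_out")
    ro_rows = []
    for label, controls in cfg.control_sets.items():
        ctrl = [adjusted.measure(c) for c in controls]
        for plabel in scores:
            res = assoc.regress_out_and_associate(
                scores[plabel], adjusted.measure(focal), ctrl,
                m=cfg.m_tests_per_measure, predictor_label=plabel,
                measure_label=f"{focal}|{label}")
            ro_rows.append({"predictor": res.predictor, "measure": res.measure,
                            "r": res.r, "N": res.N,
                            "p_one_tailed": res.p_one_tailed,
                            "nominal_sig": res.nominal,
                            "bonferroni_sig": res.bonferroni})
    regress_df = pd.DataFrame(ro_rows)
    regress_df.to_csv(out / "regress_out.csv", index=False)

    # --- power annex ------------------------------------------------------
    stage("power")
    pw_rows = []
    for n, r in cfg.power_designs:
        q = power_mod.PowerQuery(n=n)
        det_r, det_pct = power_mod.detectable_effect(q)
        pw_rows.append({"n": n, "r_printed": r,
                        "pct_variance": power_mod.r_to_pct_variance(r),
                        "power_df1_one_tailed": power_mod.power_correlation_test(r, q),
                        "power_df2": power_mod.power_correlation_test(
                            r, power_mod.PowerQuery(n=n, df=2, tails=2)),
                        "detectable_r_80pct": det_r,
                        "detectable_pct_80pct": det_pct})
    power_df = pd.DataFrame(pw_rows)
    power_df.to_csv(out / "power.csv", index=False)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)

    return {"genotypes": gm, "phenotypes": adjusted, "truth": truth,
            "qc_report": report, "scores": scores,
            "association_table": table_df, "regress_out": regress_df,
            "power": power_df, "log": log}
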