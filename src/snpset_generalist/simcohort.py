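"""Synthetic cohort generator with a generalist-genes covariance structure.

The generator emulates a genotyped developmental cohort: a few thousand
unrelated children typed on a small panel of unlinked SNPs (in
Hardy-Weinberg equilibrium by construction), a focal quantitative trait to
which the panel contributes a few percent of variance, and companion traits
whose share of that genetic signal is scaled by a genetic-generality
coefficient rho in [0, 1].

Generative model.  Genotype dosages are i.i.d. Binomial(2, maf).  Effects are
calibrated so the panel explains ``target_r**2`` of the focal trait's
variance, with equal per-SNP variance contributions:

    sum_j 2 p_j (1 - p_j) beta_j^2 = target_r^2.

With Z the standardized weighted genetic score, each trait t is

    y_t = rho_t * target_r * Z + sqrt(1 - (rho_t * target_r)^2) * eps_t,

so corr(y_t, Z) = rho_t * target_r exactly, and the expected correlation with
the *unweighted* SNP-set score is rho_t * target_r * corr(S, Z), an
attenuation of about 1-2% with MAFs in 0.1-0.5.  Genetically null traits
(rho = 0) may instead mix a share of the focal trait's residual into their
noise, producing a phenotypic correlation with the focal trait but none with
the genotypes.  Sex and age-at-testing effects are added last; missingness
(whole-plex dropouts, per-call genotype losses, per-cell phenotype losses)
is injected completely at random.

All randomness flows from one integer seed through numpy ``SeedSequence``
spawning, so the genotype, trait, covariate and missingness streams are
reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GenotypeMatrix, MISSING_CALL, PhenotypeTable, SnpInfo
from .snpset import additive_matrix

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"),
                 ("A", "T"), ("C", "G")]
DEFAULT_PLEXES = ("plex26", "plex33", "plex36", "taqman")


@dataclass(frozen=True)
class TraitSpec:
    """One simulated measure.

    ``rho`` scales the trait's loading on the shared genetic path (a genetic
    correlation with the focal trait under this model).
    ``phenotypic_noise_link`` mixes the focal trait's residual into this
    trait's noise — used for genetically null traits that are nonetheless
    phenotypically correlated with the focal trait.  ``age_mean`` centres the
    trait's age-at-testing column (years).
    """

    label: str
    rho: float
    phenotypic_noise_link: float = 0.0
    age_mean: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValidationError(f"{self.label}: rho={self.rho} outside [0,1]")
        if not 0 <= self.phenotypic_noise_link < 1:
            raise ValidationError(
                f"{self.label}: phenotypic_noise_link outside [0,1)")


@dataclass(frozen=True)
class MissingnessSpec:
    plex_dropout_rate: float = 0.0  # per (individual, plex): whole plex lost
    snp_miss_rate: float = 0.0      # per remaining call
    pheno_miss_rate: float = 0.0    # per measure cell

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0 <= v < 1:
                raise ValidationError(f"{name}={v} outside [0,1)")


@dataclass
class SimulationSpec:
    """Generative parameters for one synthetic cohort."""

    n_individuals: int = 4927
    n_snps: int = 43
    snp_mafs: tuple[float, ...] | None = None  # None: drawn U(0.1, 0.5)
    target_r: float = 0.179
    trait_specs: list[TraitSpec] = field(default_factory=list)
    sex_effect: float = 0.2       # standardized male-female mean difference
    age_half_range: float = 0.5   # ages uniform in age_mean +/- this (years)
    age_slope: float = 0.25       # standardized effect per year of age
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    plexes: tuple[str, ...] = DEFAULT_PLEXES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_r < 1:
            raise ValidationError(f"target_r={self.target_r} outside [0,1)")
        if self.snp_mafs is not None:
            self.snp_mafs = tuple(float(m) for m in self.snp_mafs)
            if any(not 0 < m <= 0.5 for m in self.snp_mafs):
                raise ValidationError("MAFs must be in (0, 0.5]")
            self.n_snps = len(self.snp_mafs)
        if not self.trait_specs:
            self.trait_specs = [TraitSpec("trait", 1.0)]
        labels = [t.label for t in self.trait_specs]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate trait labels")
        for t in self.trait_specs:
            if t.rho * self.target_r >= 1:
                raise ValidationError(f"{t.label}: rho*target_r >= 1")

    @property
    def focal_label(self) -> str:
        return self.trait_specs[0].label


def teds_like_spec(seed: int = 0, n_individuals: int = 4927,
                   missingness: MissingnessSpec | None = None
                   ) -> SimulationSpec:
    """The default study-like cohort: 43 unlinked SNPs explaining 3.2% of a
    focal age-10 mathematics composite (r = 0.179), companion maths measures
    and cross-trait measures scaled by published genetic correlations, two
    genetically null but phenotypically linked behavioural traits, modest
    sex/age effects, and plex-structured missingness."""
    r = 0.179

    def link(rho: float, r_p: float) -> float:
        # residual-mixing coefficient giving corr(y_t, y_focal) = r_p once
        # the genetic-path contribution rho * r^2 is accounted for
        a_t, a_0 = rho * r, r
        return (r_p - a_t * a_0) / np.sqrt((1 - a_t ** 2) * (1 - a_0 ** 2))

    # r_p values follow the reported phenotypic correlations with the focal
    # composite (0.65 for teacher English, not reported, is interpolated)
    traits = [
        TraitSpec("math10", 1.0, age_mean=10.0),
        TraitSpec("math_web10", 0.84, link(0.84, 0.911), age_mean=10.0),
        TraitSpec("math_teacher10", 0.84, link(0.84, 0.915), age_mean=10.0),
        TraitSpec("math9", 0.73, link(0.73, 0.633), age_mean=9.0),
        TraitSpec("math7", 0.62, link(0.62, 0.594), age_mean=7.0),
        TraitSpec("math12", 0.62, link(0.62, 0.566), age_mean=12.0),
        TraitSpec("english10", 0.79, link(0.79, 0.65), age_mean=10.0),
        TraitSpec("g10", 0.76, link(0.76, 0.596), age_mean=10.0),
        TraitSpec("reading10", 0.52, link(0.52, 0.517), age_mean=10.0),
        TraitSpec("motivation12", 0.0, link(0.0, 0.356), age_mean=12.0),
        TraitSpec("liking12", 0.0, link(0.0, 0.448), age_mean=12.0),
    ]
    if missingness is None:
        missingness = MissingnessSpec(plex_dropout_rate=0.08,
                                      snp_miss_rate=0.01,
                                      pheno_miss_rate=0.3)
    return SimulationSpec(n_individuals=n_individuals, n_snps=43,
                          target_r=r, trait_specs=traits,
                          missingness=missingness, seed=seed)


@dataclass
class TruthRecord:
    """Realized generative truths for parameter-recovery tests."""

    seed: int
    mafs: list[float]
    betas: list[float]
    target_r: float
    expected_r: dict[str, float]        # rho_t * target_r per trait
    realized_focal_r: float             # sample corr(unweighted score, focal)
    sex_effect: float
    age_slope: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(mafs, n: int, seed_or_rng,
                       plexes: tuple[str, ...] = DEFAULT_PLEXES
                       ) -> GenotypeMatrix:
    """i.i.d. Binomial(2, maf) dosages rendered as allele-pair calls.

    SNPs are mutually independent and in Hardy-Weinberg proportions by
    construction.  The increaser allele is the dosage-counted allele, so
    calibrated positive effects orient the additive coding.  Plex labels are
    assigned round-robin.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValidationError("MAFs must be in (0, 0.5]")
    rng = _rng(seed_or_rng)
    dosages = rng.binomial(2, mafs, size=(n, len(mafs)))
    snps, calls = [], np.empty((n, len(mafs)), dtype="<U2")
    for j, p in enumerate(mafs):
        a, b = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        snps.append(SnpInfo(snp_id=f"rs{1000 + j}", chrom=str(j % 22 + 1),
                            pos=10_000 * (j + 1), allele_a=a, allele_b=b,
                            increaser_allele=b, plex=plexes[j % len(plexes)]))
        glyphs = np.array([a + a, a + b, b + b], dtype="<U2")
        calls[:, j] = glyphs[dosages[:, j]]
    return GenotypeMatrix([f"ind{i:05d}" for i in range(n)], snps, calls)


def calibrate_effects(mafs, target_r: float) -> np.ndarray:
    """Equal-contribution per-SNP effects: each SNP contributes
    ``target_r^2 / m`` of unit trait variance, so
    ``beta_j = target_r / sqrt(m * 2 p_j (1 - p_j))``; all positive."""
    mafs = np.asarray(mafs, dtype=float)
    if not 0 <= target_r < 1:
        raise ValueError(f"target_r={target_r} outside [0, 1)")
    if target_r == 0:
        return np.zeros(len(mafs))
    return target_r / np.sqrt(len(mafs) * 2 * mafs * (1 - mafs))


def simulate_traits(gm: GenotypeMatrix, betas, spec: SimulationSpec,
                    seed_or_rng) -> tuple[PhenotypeTable, TruthRecord]:
    """Draw all trait values, sex and ages for the cohort in ``gm``.

    Requires complete genotypes (missingness is injected afterwards).
    """
    rng = _rng(seed_or_rng)
    n = gm.n_individuals
    betas = np.asarray(betas, dtype=float)
    dosage = additive_matrix(gm)
    mafs = dosage.mean(axis=0) / 2  # realized frequencies only for centring
    centred = dosage - dosage.mean(axis=0)
    raw = centred @ betas
    sd = raw.std(ddof=0)
    Z = raw / sd if sd > 0 else np.zeros(n)

    sex = rng.integers(0, 2, size=n)
    eps_focal = rng.standard_normal(n)
    data = {"sex": sex}
    expected = {}
    score = dosage.sum(axis=1)
    realized_focal_r = np.nan
    for k, t in enumerate(spec.trait_specs):
        a = t.rho * spec.target_r
        if abs(a) >= 1:
            raise ValidationError(f"{t.label}: |rho*target_r| >= 1")
        eps = eps_focal if k == 0 else rng.standard_normal(n)
        if t.phenotypic_noise_link > 0:
            lk = t.phenotypic_noise_link
            eps = lk * eps_focal + np.sqrt(1 - lk * lk) * eps
        y = a * Z + np.sqrt(1 - a * a) * eps
        if k == 0 and np.std(score) > 0 and np.std(y) > 0:
            realized_focal_r = float(np.corrcoef(score, y)[0, 1])
        age = rng.uniform(t.age_mean - spec.age_half_range,
                          t.age_mean + spec.age_half_range, size=n)
        y = y + spec.sex_effect * sex + spec.age_slope * (age - age.mean())
        data[t.label] = y
        data[f"age_{t.label}"] = age
        expected[t.label] = a

    df = pd.DataFrame(data, index=pd.Index(gm.individual_ids,
                                           name="individual_id"))
    table = PhenotypeTable(df, measures=[t.label for t in spec.trait_specs])
    truth = TruthRecord(seed=spec.seed, mafs=[float(m) for m in mafs],
                        betas=[float(b) for b in betas],
                        target_r=spec.target_r, expected_r=expected,
                        realized_focal_r=realized_focal_r,
                        sex_effect=spec.sex_effect, age_slope=spec.age_slope)
    return table, truth


def inject_missingness(gm: GenotypeMatrix, table: PhenotypeTable,
                       miss: MissingnessSpec, seed_or_rng
                       ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Missing-completely-at-random losses: whole-plex individual dropouts,
    per-call genotype losses, per-cell phenotype losses.  Sex and age columns
    stay complete (registry covariates)."""
    rng = _rng(seed_or_rng)
    gm = gm.copy()
    table = table.copy()
    n, m = gm.n_individuals, gm.n_snps
    if m and miss.plex_dropout_rate > 0:
        plex_of = np.array([s.plex for s in gm.snps])
        for p in dict.fromkeys(plex_of):  # stable order
            drop = rng.random(n) < miss.plex_dropout_rate
            gm.calls[np.ix_(drop, plex_of == p)] = MISSING_CALL
    if m and miss.snp_miss_rate > 0:
        gm.calls[rng.random((n, m)) < miss.snp_miss_rate] = MISSING_CALL
    if miss.pheno_miss_rate > 0:
        for col in table.measures:
            lost = rng.random(len(table.data)) < miss.pheno_miss_rate
            table.data.loc[lost, col] = np.nan
    return gm, table


def simulate_cohort(spec: SimulationSpec
                    ) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Full cohort draw, reproducible from ``spec`` (including its seed)."""
    ss = np.random.SeedSequence(spec.seed)
    maf_rng, geno_rng, trait_rng, miss_rng = map(np.random.default_rng,
                                                 ss.spawn(4))
    mafs = (np.asarray(spec.snp_mafs) if spec.snp_mafs is not None
            else maf_rng.uniform(0.1, 0.5, size=spec.n_snps))
    gm = simulate_genotypes(mafs, spec.n_individuals, geno_rng,
                            plexes=spec.plexes)
    betas = calibrate_effects(mafs, spec.target_r)
    table, truth = simulate_traits(gm, betas, spec, trait_rng)
    truth.mafs = [float(m) for m in mafs]  # generative, not realized
    gm, table = inject_missingness(gm, table, spec.missingness, miss_rng)
    return gm, table, truth
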