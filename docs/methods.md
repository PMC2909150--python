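# Methods

This package re-creates, as tested library code, the analysis pipeline used
to ask whether a small SNP panel nominated for one quantitative trait also
predicts related traits and the same trait at other ages — the
"generalist genes" question. Because the original cohort's individual-level
data are access-restricted, the pipeline is exercised end-to-end on a
synthetic cohort generator whose covariance structure embodies the published
quantitative-genetic parameters. This note records the models, the defaults
and why, the numerical choices, and what the synthetic results do and do not
establish.

## Genotype model and quality control

Genotypes are unphased biallelic calls on a panel of unlinked autosomal
SNPs. Three QC rules are applied in a fixed order:

1. **Within-plex individual call rate** (default ≥ 0.70). Multiplexed
   genotyping assays fail per (individual, plex) block, so call-rate
   screening is done per plex: an individual below threshold has that whole
   plex masked; one below threshold on *every* plex is dropped.
2. **SNP call rate** (default ≥ 0.95, strict inequality removes; a SNP at
   exactly the boundary is retained). Rates are computed after the plex
   masking, **among attempted samples**: individuals with zero calls on a
   plex are whole-assay failures already removed from that plex's analyses,
   and counting them against every SNP in the plex would remove the entire
   panel whenever per-plex failure rates reach the realistic ~10%.
3. **Hardy-Weinberg equilibrium** (exact test; removal at p ≤ 0.01, i.e.
   panels are kept while p > α).

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count has a known distribution under random mating, and the
p-value sums the probabilities of all heterozygote counts no more probable
than the observed one. Probabilities are computed in log space with a
`gammaln` kernel and renormalized, which is stable to the thousands of
samples relevant here; the test suite pins it to an exhaustive
rational-arithmetic enumeration to 1e-12 on tables up to n = 200. A
chi-square variant is available behind a flag; the exact test is the default
because it is well-defined at small expected counts and conservative
(rejection rate ≤ α under the null), which the suite verifies by
simulation. Whether the original HWE screen used the pre- or
post-individual-filter sample is not recoverable; we test post-filter.

## SNP-set scores

Each genotype is additively coded 0/1/2 as the number of copies of the
SNP's *increaser allele* (the allele associated with higher trait values in
the discovery stage), so every predictor is oriented toward positive
association before any phenotype is seen. A SNP-set score is the unweighted
sum of these codes over a fixed panel: a k-SNP set spans [0, 2k] (10-SNP set
0–20, 43-SNP set 0–86).

Two missing-data policies:

* **complete-only** — individuals missing any panel genotype are excluded
  (scores are integers);
* **mean substitution** — individuals missing at most `max_missing`
  genotypes (default 3 of 43) have each missing code replaced by that SNP's
  mean code over individuals with a call, computed per run from the cohort
  in hand. Substitution leaves every per-SNP mean unchanged (asserted to
  1e-12) but shrinks score variance relative to complete data — a known cost
  of the method that the tests reproduce.

No LD-based imputation is attempted (the panel is unlinked by design, so
there is nothing to impute from); an advisory warning is logged if any
pairwise genotype r² in a set exceeds 0.2. Coordinates are 1-based and no
strand flipping is performed: increaser alleles must be stated on the same
strand as the calls.

## Phenotype preparation

Measures are prepared by (1) residualizing the raw measure on sex (0/1) and
its age-at-testing column (years, continuous) by OLS with intercept on
complete cases, then (2) re-standardizing the residuals to mean 0, SD 1
(n−1 denominator). Residualize-then-standardize makes all downstream
correlations scale-free; the re-standardization is a documented flag since
the original order is not recoverable from the text. A constant covariate
(e.g. an age column with a single value) is dropped from the design with a
warning rather than raising; a genuinely rank-deficient design raises.

Composites follow standardize → average → re-standardize. Availability
rules: `fallback_single` lets an individual with only one component enter
with that standardized component (the maths composite); `require_all` blanks
any individual missing a component (the g composite built from four tests).
Components are weighted equally.

## Association testing

Every cell is a Pearson product-moment correlation on pairwise-complete
cases (per-cell N varies with missingness; no listwise deletion).
Inference is one-tailed in the positive direction — the coding already fixes
the expected sign — via the upper tail of t = r·sqrt((N−2)/(1−r²)) on N−2
degrees of freedom; a wrong-direction r gives p > 0.5. The t formulation
(not Fisher-z) is pinned because the two differ negligibly at these N but
tests need a single convention. Flags: nominal at p < 0.05, Bonferroni at
p < 0.05/m with m = 5 (two SNP sets plus three single SNPs per measure).
The report also carries a phenotypic-correlation row (each measure vs the
focal composite, r and N only).

Specificity ("regress-out") analyses residualize the *phenotype* on the
control measures and re-associate, mirroring the original wording; a full
partial correlation (both sides residualized) is available behind a flag.
N shrinks to the joint-complete sample.

## Power

Effect sizes convert as %variance = 100·r² under the additive QTL model
(MAF enters documentation only: r² fully determines the noncentrality).
Analytic power uses noncentral distributions with NCP = n·r²: df = 1 is the
additive/trend test (one-tailed normal or noncentral-t formulations, which
agree within 0.01 at the relevant n; a scipy noncentral-t underflow at very
large df falls back to the normal form), df = 2 is the genotypic
(additive + dominance) test. `detectable_effect` inverts power by Brent
root-finding to |Δpower| < 1e-6.

The published 80%-power statements pin (N, r) at (2112, 0.067),
(1431, 0.084) and (3891, 0.05). The classic genetic power calculator's
internal settings are not stated, so the module exposes α, tails and df as
parameters and ships a calibration table: **df = 2 at α = 0.05 reproduces
~0.80 for all three designs simultaneously** (0.793, 0.819, 0.804 — the
residual spread is consistent with print-rounding of r), while the df = 1
one-tailed test gives ~0.92–0.93. Library defaults remain α = 0.05, df = 1,
one-tailed for ordinary correlation tests; only the r ↔ %variance
conversions are treated as exact.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

**Genotypes.** n = 4927 unrelated individuals (the post-QC genotyped
sampling frame) × 43 SNPs, dosages i.i.d. Binomial(2, MAF) — HWE and
linkage equilibrium hold by construction. Per-SNP MAFs are not published;
they are drawn once per cohort from Uniform(0.1, 0.5), a typical range for
assayable common variants.

**Effects.** Betas are calibrated so the panel explains target_r² = 3.2% of
the focal trait (target_r = 0.179), with equal per-SNP variance
contributions: βⱼ = target_r / sqrt(m·2pⱼ(1−pⱼ)). With Z the standardized
weighted genetic score, trait t is

    y_t = ρ_t·target_r·Z + sqrt(1 − (ρ_t·target_r)²)·ε_t ,

so corr(y_t, Z) = ρ_t·target_r exactly. ρ maps the published genetic
correlations one-to-one onto trait loadings: 0.84 for within-domain
components, 0.73/0.62 across ages, 0.79/0.76/0.52 across abilities, 0 for
the behavioural traits. Two consequences worth knowing:

* The analysis scores are *unweighted* sums while Z is inverse-SD weighted,
  so the expected score–trait correlation is ρ_t·target_r·corr(S, Z) ≈
  0.98–0.99 of nominal — an attenuation of ~0.004 at target_r = 0.179,
  inside the ±0.01 bias budget the recovery tests enforce (measured mean
  over 200 cohorts of 4000: 0.177).
* Equal contributions make the 10-SNP subset weaker than the real
  replicated sub-panel (expected r ≈ sqrt(10/43)·target_r ≈ 0.086 vs the
  reported 0.167); the generator models the panel's total signal, not the
  discovery-stage enrichment of its best members.

**Phenotypic links.** Residual mixing gives traits phenotypic correlation
with the focal composite beyond the genetic path: ε_t is replaced by
λ·ε_focal + sqrt(1−λ²)·fresh. λ is solved per trait so realized r_p matches
the published phenotypic-correlation row (0.91/0.92 for the components,
0.52–0.64 across ages and abilities; teacher English, unreported, is
interpolated at 0.65). The genetically null behavioural traits use the same
mechanism (r_p 0.356/0.448) — phenotypically correlated, genetically zero —
which is what makes the null-trait check meaningful.

**Covariates and missingness.** Sex is Bernoulli(1/2) with a 0.2 SD mean
shift; age-at-testing is uniform within ±0.5 y of each measure's target age
with a 0.25 SD/year slope — modest, plausible registry effects whose exact
values are not published. Missingness is completely at random:
whole-plex dropouts at 8% per (individual, plex) (the reported per-plex
removals are ~4–12% of the frame), 1% per-call genotype loss, 30%
per-measure phenotype loss (reported per-measure Ns vary far more; 30%
yields focal-analysis Ns near the reported ~1900–2500 after score
eligibility). All randomness derives from one integer seed via numpy
`SeedSequence` spawning (separate genotype/trait/missingness streams), so
cohorts are bit-reproducible.

**What the generator does not emulate.** Twin structure (the genotyped
sample is one member per pair), LD, ascertainment of the discovery pools,
population stratification, non-additive effects, informative (non-MCAR)
missingness, measurement unreliability, and per-SNP effect heterogeneity.
Passing recovery tests therefore show the *estimator machinery* is
calibrated and unbiased under the assumed covariance structure — not that
the original associations are true, nor how the pipeline behaves under
model violations.

## Experiment sizes and expectations

The repeated-simulation experiments (shared by the test suite and
`analysis/07_calibration_experiments.py`) use: 1000 null cohorts of n = 500
for type-I calibration (one-tailed nominal rate ≈ 0.05); 200 cohorts of
n = 4000 for recovery of target_r = 0.179 (band ±0.035 ≈ 2.2/sqrt(n) at its
nominal ~97% coverage; replicate mean within ±0.01); 200 cohorts at the
default n = 4927 for the attenuation-ordering experiment; 100 cohorts of
n = 2000 for regress-out attenuation. The ordering experiment checks every
trait pair whose ρ values differ by at least 0.2: with r gaps of
ρ-gap × 0.179 against a sampling SD of ~sqrt(2/n) for a difference of two
estimates, closer pairs are not statistically separable at any plausible
cohort size (adjacent gaps of 0.1 give ~0.8σ separations), so the qualifying
pairs are the resolvable expression of the attenuation pattern. Power
formulas are checked against 20,000-replicate bivariate-normal Monte Carlo
at the two largest published designs (agreement within 1.5 points; measured
~0.2).

## Known limitations

* ped/map carries no increaser-allele or plex metadata; a panel TSV is
  required alongside every genotype dialect.
* Multi-allelic VCF records, binary PLINK and dosage formats are out of
  scope.
* The QC report logs per-plex removals but re-typing of failed assays (a
  lab step) is not modeled; failures go straight to masking.
* `hwe_exact_p` is exact but O(allele count) per SNP; fine for panels of
  tens of SNPs, not meant for genome-wide screens.
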