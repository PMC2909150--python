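# Full study-like analysis on a simulated cohort: 4927 unrelated children,
# 43 unlinked SNPs explaining 3.2% of the focal maths composite, companion
# traits scaled by genetic correlations, two genetically null behavioural
# traits, sex/age effects and plex-structured missingness.
out_dir: results/teds_like
seed: 0

simulation:
  n_individuals: 4927
  n_snps: 43
  target_r: 0.179
  sex_effect: 0.2
  age_slope: 0.25
  age_half_range: 0.5
  missingness:
    plex_dropout_rate: 0.08
    snp_miss_rate: 0.01
    pheno_miss_rate: 0.3
  # phenotypic_noise_link values are residual-mixing coefficients chosen so
  # realized phenotypic correlations with math10 match the reported r_p row
  traits:
    - {label: math10, rho: 1.0, age_mean: 10.0}
    - {label: math_web10, rho: 0.84, phenotypic_noise_link: 0.9089, age_mean: 10.0}
    - {label: math_teacher10, rho: 0.84, phenotypic_noise_link: 0.9130, age_mean: 10.0}
    - {label: math9, rho: 0.73, phenotypic_noise_link: 0.6250, age_mean: 9.0}
    - {label: math7, rho: 0.62, phenotypic_noise_link: 0.5872, age_mean: 7.0}
    - {label: math12, rho: 0.62, phenotypic_noise_link: 0.5586, age_mean: 12.0}
    - {label: english10, rho: 0.79, phenotypic_noise_link: 0.6414, age_mean: 10.0}
    - {label: g10, rho: 0.76, phenotypic_noise_link: 0.5865, age_mean: 10.0}
    - {label: reading10, rho: 0.52, phenotypic_noise_link: 0.5108, age_mean: 10.0}
    - {label: motivation12, rho: 0.0, phenotypic_noise_link: 0.3618, age_mean: 12.0}
    - {label: liking12, rho: 0.0, phenotypic_noise_link: 0.4554, age_mean: 12.0}

qc:
  min_individual_plex_call_rate: 0.70
  min_snp_call_rate: 0.95
  hwe_alpha: 0.01

snpset_sizes: [10, 43]
max_missing_full_set: 3
n_single_snps: 3
m_tests_per_measure: 5
focal_measure: math10
control_sets:
  g_controlled: [g10]
  reading_controlled: [reading10]
  g_and_reading_controlled: [g10, reading10]
  all_controlled: [g10, reading10, english10]
power_designs:
  - [2112, 0.067]
  - [1431, 0.084]
  - [3891, 0.05]
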