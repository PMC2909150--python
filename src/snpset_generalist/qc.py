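"""Genotype quality control.

Three rules, applied in order:

1. **Within-plex individual call rate** — an individual called on fewer than
   70% of the SNPs in a genotyping plex has all of that plex's calls masked;
   individuals failing every plex are dropped from the matrix.
2. **SNP call rate** — SNPs called in fewer than 95% of individuals (after
   the plex masking) are removed; a SNP at exactly the threshold is kept.
3. **Hardy-Weinberg equilibrium** — SNPs whose exact-test p-value is at or
   below 0.01 are removed (panels are kept only while p > alpha).

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count follows a known distribution under random mating, and the
p-value sums the probabilities of all heterozygote counts no more probable
than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError, DegenerateInputError
from .io import GenotypeMatrix, MISSING_CALL


@dataclass(frozen=True)
class QcConfig:
    min_individual_plex_call_rate: float = 0.70
    min_snp_call_rate: float = 0.95
    hwe_alpha: float = 0.01
    hwe_test: str = "exact"  # or "chisq"

    def __post_init__(self) -> None:
        for name in ("min_individual_plex_call_rate", "min_snp_call_rate",
                     "hwe_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if self.hwe_test not in ("exact", "chisq"):
            raise ConfigError(f"unknown HWE test {self.hwe_test!r}")


@dataclass
class QcReport:
    """Audit trail of every QC action."""

    plex_removals: dict[str, list[str]] = field(default_factory=dict)
    removed_individuals: list[str] = field(default_factory=list)
    removed_snps: dict[str, str] = field(default_factory=dict)  # id -> reason
    snp_call_rates: dict[str, float] = field(default_factory=dict)
    hwe_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def plex_removal_counts(self) -> dict[str, int]:
        return {p: len(ids) for p, ids in self.plex_removals.items()}

    def merge(self, other: "QcReport") -> None:
        for p, ids in other.plex_removals.items():
            self.plex_removals.setdefault(p, []).extend(ids)
        self.removed_individuals.extend(other.removed_individuals)
        self.removed_snps.update(other.removed_snps)
        self.snp_call_rates.update(other.snp_call_rates)
        self.hwe_pvalues.update(other.hwe_pvalues)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["plex_removal_counts"] = self.plex_removal_counts
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts; heterozygote counts share the
    parity of the minor-allele count.  Probabilities are computed in log space
    and the p-value sums all heterozygote counts whose probability does not
    exceed the observed one.  Returns a value in (0, 1].
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise DegenerateInputError("all genotype counts are zero")
    n_a = 2 * n_AA + n_Aa  # copies of allele A
    n_b = 2 * n_aa + n_Aa
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: a single possible table
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = _log_het_prob(hets, n, rare)
    logp -= _logsumexp(logp)  # exact normalization
    obs = logp[np.searchsorted(hets, n_Aa)]
    # tolerance guards against ties lost to rounding
    include = logp <= obs + 1e-10
    if include.all():
        return 1.0  # observed table is modal: every table counts
    return min(float(np.exp(logp[include]).sum()), 1.0)


def _log_het_prob(hets, n, rare):
    """Unnormalized log-probability of each heterozygote count given the
    allele counts (multinomial/hypergeometric kernel)."""
    common = 2 * n - rare
    n_rr = (rare - hets) // 2
    n_cc = (common - hets) // 2
    return (hets * np.log(2)
            - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1))


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.exp(x - m).sum())


def hwe_chisq_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise DegenerateInputError("all genotype counts are zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, 1))


def genotype_counts(gm: GenotypeMatrix, j: int) -> tuple[int, int, int]:
    """(hom allele_a, het, hom allele_b) counts for SNP column ``j``."""
    snp = gm.snps[j]
    col = gm.calls[:, j]
    obs = col[col != MISSING_CALL]
    a, b = snp.allele_a, snp.allele_b
    n_aa = int(np.sum(obs == a + a))
    n_bb = int(np.sum(obs == b + b))
    n_ab = len(obs) - n_aa - n_bb
    return n_aa, n_ab, n_bb


# ---------------------------------------------------------------------------
# Filters

def filter_individuals_by_plex(gm: GenotypeMatrix, cfg: QcConfig = QcConfig()
                               ) -> tuple[GenotypeMatrix, QcReport]:
    """Mask, per individual and plex, all calls of any plex on which the
    individual's call rate falls below the threshold; drop individuals who
    fail every plex."""
    plexes: dict[str, list[int]] = {}
    for j, s in enumerate(gm.snps):
        plexes.setdefault(s.plex, []).append(j)
    for p, cols in plexes.items():
        if not cols:
            raise ConfigError(f"plex {p!r} has no SNPs")

    report = QcReport(plex_removals={p: [] for p in plexes})
    calls = gm.calls.copy()
    missing = gm.missing_mask()
    failed_all = np.ones(gm.n_individuals, dtype=bool)
    for p, cols in plexes.items():
        rate = 1.0 - missing[:, cols].mean(axis=1)
        fail = rate < cfg.min_individual_plex_call_rate
        for i in np.flatnonzero(fail):
            report.plex_removals[p].append(gm.individual_ids[i])
            calls[i, cols] = MISSING_CALL
        failed_all &= fail
    keep = ~failed_all
    report.removed_individuals = [gm.individual_ids[i]
                                  for i in np.flatnonzero(failed_all)]
    out = GenotypeMatrix([gm.individual_ids[i] for i in np.flatnonzero(keep)],
                         list(gm.snps), calls[keep])
    return out, report


def filter_snps_by_call_rate(gm: GenotypeMatrix, cfg: QcConfig = QcConfig()
                             ) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs called in strictly fewer than ``min_snp_call_rate`` of
    attempted individuals; a SNP exactly at the boundary is retained.

    Individuals with no call on any SNP of a plex have been removed from that
    plex's analyses (whole-assay failures), so they are excluded from the
    denominator of that plex's SNP call rates rather than counted against
    every SNP in it.
    """
    if gm.n_individuals == 0:
        raise DegenerateInputError("no individuals in matrix")
    missing = gm.missing_mask()
    plexes: dict[str, list[int]] = {}
    for j, s in enumerate(gm.snps):
        plexes.setdefault(s.plex, []).append(j)
    rates = np.ones(gm.n_snps)
    for cols in plexes.values():
        attempted = ~missing[:, cols].all(axis=1)
        n_att = int(attempted.sum())
        if n_att == 0:
            rates[cols] = 0.0
            continue
        rates[cols] = 1.0 - missing[np.ix_(attempted, cols)].mean(axis=0)
    report = QcReport()
    keep = []
    for j, s in enumerate(gm.snps):
        report.snp_call_rates[s.snp_id] = float(rates[j])
        if rates[j] < cfg.min_snp_call_rate:
            report.removed_snps[s.snp_id] = "call_rate"
        else:
            keep.append(s.snp_id)
    return gm.subset(snps=keep), report


def filter_snps_by_hwe(gm: GenotypeMatrix, cfg: QcConfig = QcConfig()
                       ) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs out of Hardy-Weinberg equilibrium (p <= alpha)."""
    test = hwe_exact_p if cfg.hwe_test == "exact" else hwe_chisq_p
    report = QcReport()
    keep = []
    for j, s in enumerate(gm.snps):
        counts = genotype_counts(gm, j)
        if sum(counts) == 0:
            p = 1.0  # no observed genotypes: nothing to test
        else:
            p = test(*counts)
        report.hwe_pvalues[s.snp_id] = p
        if p <= cfg.hwe_alpha:
            report.removed_snps[s.snp_id] = "hwe"
        else:
            keep.append(s.snp_id)
    return gm.subset(snps=keep), report


def run_qc(gm: GenotypeMatrix, cfg: QcConfig = QcConfig()
           ) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC: individual-by-plex masking, then SNP call rate, then HWE.

    Call rates for the SNP filter are computed after the plex masking.
    Idempotent: running QC on its own output changes nothing.
    """
    gm1, rep = filter_individuals_by_plex(gm, cfg)
    gm2, rep2 = filter_snps_by_call_rate(gm1, cfg)
    rep.merge(rep2)
    gm3, rep3 = filter_snps_by_hwe(gm2, cfg)
    rep.merge(rep3)
    return gm3, rep
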