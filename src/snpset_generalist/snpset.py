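"""Direction-aware additive SNP coding and unweighted SNP-set scores.

Each genotype is coded as the number of copies of the SNP's increaser allele
(0 = homozygote associated with lower trait values, 1 = heterozygote,
2 = increaser homozygote).  A SNP-set score sums these codes over a fixed
panel, so a k-SNP set ranges over [0, 2k].

Two missing-data policies are supported, mirroring how small genotyped panels
are analysed in practice:

* ``COMPLETE_ONLY`` — only individuals with a call at every SNP in the set
  receive a score (necessarily an integer);
* ``MEAN_SUBSTITUTE(max_missing)`` — individuals missing at most
  ``max_missing`` genotypes have each missing code replaced by that SNP's
  mean code across individuals with a call ("mean substitution"), which
  leaves per-SNP means untouched but shrinks score variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GenotypeMatrix, MISSING_CALL, SnpInfo

logger = logging.getLogger(__name__)

COMPLETE_ONLY = "complete_only"
MEAN_SUBSTITUTE = "mean_substitute"


@dataclass(frozen=True)
class SnpSetDefinition:
    name: str
    snp_ids: tuple[str, ...]
    policy: str = COMPLETE_ONLY
    max_missing: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError(f"{self.name}: duplicate SNP ids")
        if self.policy not in (COMPLETE_ONLY, MEAN_SUBSTITUTE):
            raise ValidationError(f"{self.name}: unknown policy {self.policy!r}")
        if self.policy == MEAN_SUBSTITUTE and not (
                0 <= self.max_missing < len(self.snp_ids)):
            raise ValidationError(
                f"{self.name}: max_missing={self.max_missing} must be in "
                f"[0, {len(self.snp_ids)})")

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def encode_additive(call: str, snp: SnpInfo) -> float:
    """Additive code of one call: copies of the increaser allele, or NaN."""
    if call == MISSING_CALL:
        return float("nan")
    allowed = {snp.allele_a, snp.allele_b}
    if len(call) != 2 or not set(call) <= allowed:
        raise ValidationError(
            f"{snp.snp_id}: call {call!r} uses alleles outside "
            f"{snp.allele_a}/{snp.allele_b}")
    return float(call.count(snp.increaser_allele))


def additive_matrix(gm: GenotypeMatrix, snp_ids=None) -> np.ndarray:
    """Vectorized additive coding: (n_individuals, k) float matrix with NaN
    for missing calls."""
    if snp_ids is None:
        snp_ids = gm.snp_ids
    cols = []
    for sid in snp_ids:
        j = gm.snp_index(sid)
        snp = gm.snps[j]
        col = gm.calls[:, j]
        inc = snp.increaser_allele
        other = snp.allele_b if inc == snp.allele_a else snp.allele_a
        lut = {inc + inc: 2.0, inc + other: 1.0, other + inc: 1.0,
               other + other: 0.0, MISSING_CALL: np.nan}
        uniq, inverse = np.unique(col, return_inverse=True)
        bad = [u for u in uniq if u not in lut]
        if bad:
            i = int(np.flatnonzero(col == bad[0])[0])
            raise ValidationError(
                f"{snp.snp_id}: call {bad[0]!r} of individual "
                f"{gm.individual_ids[i]!r} uses alleles outside "
                f"{snp.allele_a}/{snp.allele_b}")
        codes = np.array([lut[u] for u in uniq])[inverse]
        cols.append(codes)
    return np.column_stack(cols) if cols else np.empty((gm.n_individuals, 0))


def score_bounds(defn: SnpSetDefinition) -> tuple[float, float]:
    """(min, max) attainable score: (0, 2k) for a k-SNP set."""
    return 0.0, 2.0 * defn.size


def _ld_advisory(codes: np.ndarray, defn: SnpSetDefinition,
                 threshold: float = 0.2) -> None:
    """Summing assumes the panel is free of linkage disequilibrium; warn if
    any pairwise genotype r-squared looks high."""
    if codes.shape[1] < 2 or codes.shape[0] < 10:
        return
    with np.errstate(invalid="ignore"):
        df = pd.DataFrame(codes)
        r2 = df.corr().to_numpy() ** 2
    np.fill_diagonal(r2, 0.0)
    jmax = np.unravel_index(np.nanargmax(r2), r2.shape)
    if r2[jmax] > threshold:
        logger.warning(
            "SNP set %s: pairwise genotype r^2 = %.3f between %s and %s "
            "exceeds %.2f; summed scores assume no linkage disequilibrium",
            defn.name, r2[jmax], defn.snp_ids[jmax[0]], defn.snp_ids[jmax[1]],
            threshold)


def build_snpset_scores(gm: GenotypeMatrix, defn: SnpSetDefinition
                        ) -> pd.DataFrame:
    """Per-individual SNP-set scores.

    Returns a DataFrame indexed by individual ID with columns ``score``
    (NaN for ineligible individuals), ``n_substituted`` and ``eligible``.
    Substitution means are computed per SNP over all individuals in ``gm``
    with a non-missing call.
    """
    codes = additive_matrix(gm, defn.snp_ids)
    _ld_advisory(codes, defn)
    n_missing = np.isnan(codes).sum(axis=1)

    if defn.policy == COMPLETE_ONLY:
        eligible = n_missing == 0
        n_sub = np.zeros(gm.n_individuals, dtype=int)
        score = np.where(eligible, np.nansum(codes, axis=1), np.nan)
    else:
        eligible = n_missing <= defn.max_missing
        n_sub = np.where(eligible, n_missing, 0).astype(int)
        with np.errstate(invalid="ignore"):
            snp_means = np.nanmean(codes, axis=0)
        filled = np.where(np.isnan(codes), snp_means, codes)
        score = np.where(eligible, filled.sum(axis=1), np.nan)

    if not eligible.any():
        logger.warning("SNP set %s: no eligible individuals", defn.name)
    return pd.DataFrame(
        {"score": score, "n_substituted": n_sub, "eligible": eligible},
        index=pd.Index(gm.individual_ids, name="individual_id"))


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", na_rep="NA")


def read_snpset_config(path) -> list[SnpSetDefinition]:
    """Load SNP-set definitions from YAML/JSON: a list of mappings with keys
    name, snp_ids, policy, max_missing."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for item in raw:
        defs.append(SnpSetDefinition(
            name=item["name"], snp_ids=tuple(item["snp_ids"]),
            policy=item.get("policy", COMPLETE_ONLY),
            max_missing=int(item.get("max_missing", 0))))
    return defs
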