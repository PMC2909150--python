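import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpset_generalist.errors import DegenerateInputError
from snpset_generalist.io import GenotypeMatrix, MISSING_CALL
from snpset_generalist.qc import (QcConfig, filter_individuals_by_plex,
                                  filter_snps_by_call_rate,
                                  filter_snps_by_hwe, genotype_counts,
                                  hwe_chisq_p, hwe_exact_p, run_qc)
from snpset_generalist.simcohort import simulate_genotypes

from conftest import make_snp
from oracles import hwe_enumeration_p


def build_matrix(n_ind, snps, fill="AG"):
    calls = np.full((n_ind, len(snps)), "", dtype="<U2")
    for j, s in enumerate(snps):
        calls[:, j] = s.allele_a + s.allele_b
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], snps, calls)


class TestHweExact:
    def test_modal_table_gives_one(self):
        assert hwe_exact_p(25, 50, 25) == 1.0

    def test_monomorphic_gives_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0

    def test_small_table_matches_enumeration(self):
        # 7 copies of each allele; heterozygote counts {1,3,5,7}
        assert hwe_exact_p(3, 1, 3) == pytest.approx(
            hwe_enumeration_p(3, 1, 3), abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DegenerateInputError):
            hwe_exact_p(0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 70), st.integers(0, 70), st.integers(0, 60))
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_p(n_aa, n_ab, n_bb), abs=1e-12)

    def test_exact_test_is_conservative_under_hwe(self):
        """Across simulated in-equilibrium SNPs the rejection fraction at
        alpha=0.01 stays at or below ~2% (the exact test is conservative)."""
        rng = np.random.default_rng(11)
        n, n_snps = 200, 1000
        rejected = 0
        for _ in range(n_snps):
            p = rng.uniform(0.1, 0.5)
            dosage = rng.binomial(2, p, size=n)
            counts = np.bincount(dosage, minlength=3)
            pval = hwe_exact_p(counts[0], counts[1], counts[2])
            rejected += pval <= 0.01
        assert rejected / n_snps <= 0.02

    def test_chisq_variant_agrees_at_large_counts(self):
        # both tests see a strong departure the same way
        assert hwe_chisq_p(500, 100, 400) < 1e-10
        assert hwe_exact_p(500, 100, 400) < 1e-10


class TestPlexFilter:
    def _matrix_with_plex_missingness(self, n_called_in_plex26):
        snps = ([make_snp(f"a{j}", "1", 100 + j, ("A", "G"), plex="plex26")
                 for j in range(26)]
                + [make_snp(f"b{j}", "2", 500 + j, ("C", "T"), plex="plex33")
                   for j in range(4)])
        gm = build_matrix(3, snps)
        # individual 0: called on n_called_in_plex26 of the 26
        gm.calls[0, n_called_in_plex26:26] = MISSING_CALL
        return gm

    def test_rate_below_threshold_masks_whole_plex(self):
        gm = self._matrix_with_plex_missingness(18)  # 18/26 = 0.692 < 0.70
        out, report = filter_individuals_by_plex(gm)
        assert (out.calls[0, :26] == MISSING_CALL).all()
        assert (out.calls[0, 26:] != MISSING_CALL).all()
        assert report.plex_removals["plex26"] == ["i0"]

    def test_rate_at_or_above_threshold_untouched(self):
        gm = self._matrix_with_plex_missingness(19)  # 19/26 = 0.731
        out, _ = filter_individuals_by_plex(gm)
        assert int((out.calls[0] == MISSING_CALL).sum()) == 26 - 19

    def test_fully_called_individual_untouched(self):
        gm = self._matrix_with_plex_missingness(26)
        out, report = filter_individuals_by_plex(gm)
        assert np.array_equal(out.calls, gm.calls)
        assert report.removed_individuals == []

    def test_individual_failing_every_plex_removed(self):
        gm = self._matrix_with_plex_missingness(26)
        gm.calls[2, :] = MISSING_CALL
        out, report = filter_individuals_by_plex(gm)
        assert out.individual_ids == ["i0", "i1"]
        assert report.removed_individuals == ["i2"]
        assert "i2" in report.plex_removals["plex26"]
        assert "i2" in report.plex_removals["plex33"]


class TestSnpCallRate:
    def _matrix(self, n=100, n_snps=4):
        snps = [make_snp(f"s{j}", "1", 100 + j, ("A", "G")) for j in range(n_snps)]
        return build_matrix(n, snps)

    def test_below_threshold_removed(self):
        gm = self._matrix()
        gm.calls[:6, 0] = MISSING_CALL  # 94/100
        out, report = filter_snps_by_call_rate(gm)
        assert out.snp_ids == ["s1", "s2", "s3"]
        assert report.removed_snps == {"s0": "call_rate"}

    def test_exact_boundary_retained(self):
        gm = self._matrix()
        gm.calls[:5, 0] = MISSING_CALL  # exactly 95/100
        out, _ = filter_snps_by_call_rate(gm)
        assert "s0" in out.snp_ids

    def test_panel_reduction_forty_six_to_forty_three(self):
        snps = [make_snp(f"s{j}", "1", 100 + j, ("A", "G")) for j in range(46)]
        gm = build_matrix(100, snps)
        for j in (5, 17, 40):
            gm.calls[:10, j] = MISSING_CALL
        out, report = filter_snps_by_call_rate(gm)
        assert out.n_snps == 43
        assert set(report.removed_snps) == {"s5", "s17", "s40"}

    def test_plex_failures_not_counted_against_snps(self):
        """Individuals with a whole plex missing are excluded from that
        plex's SNP call-rate denominators."""
        gm = self._matrix(n=100)
        gm.calls[:30, :] = MISSING_CALL  # 30 whole-assay failures
        out, report = filter_snps_by_call_rate(gm)
        assert out.n_snps == 4
        assert all(r == 1.0 for r in report.snp_call_rates.values())


class TestHweFilter:
    def test_removes_disequilibrium_snp(self):
        snps = [make_snp("ok", "1", 1, ("A", "G")),
                make_snp("bad", "1", 2, ("C", "T"))]
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, 0.3, size=200)
        calls = np.empty((200, 2), dtype="<U2")
        calls[:, 0] = np.array(["AA", "AG", "GG"])[dosage]
        calls[:, 1] = "CT"  # all heterozygous: gross HWE violation
        gm = GenotypeMatrix([f"i{k}" for k in range(200)], snps, calls)
        out, report = filter_snps_by_hwe(gm)
        assert out.snp_ids == ["ok"]
        assert report.removed_snps == {"bad": "hwe"}
        assert report.hwe_pvalues["bad"] <= 0.01


class TestRunQc:
    def test_clean_matrix_passes_unchanged(self):
        rng = np.random.default_rng(0)
        gm = simulate_genotypes(rng.uniform(0.2, 0.5, 8), 300, rng)
        out, report = run_qc(gm)
        assert out == gm
        assert report.removed_individuals == []
        assert report.removed_snps == {}

    def test_one_offender_per_rule(self):
        rng = np.random.default_rng(1)
        gm = simulate_genotypes(rng.uniform(0.2, 0.5, 12), 200, rng,
                                plexes=("plexA",))
        # SNP 0: low call rate among attempted individuals
        gm.calls[:50, 0] = MISSING_CALL
        # SNP 1: flagrant HWE violation
        gm.calls[:, 1] = gm.snps[1].allele_a + gm.snps[1].allele_b
        # individual 0: fails every plex
        gm.calls[0, :] = MISSING_CALL
        out, report = run_qc(gm)
        assert report.removed_individuals == ["ind00000"]
        assert report.removed_snps[gm.snp_ids[0]] == "call_rate"
        assert report.removed_snps[gm.snp_ids[1]] == "hwe"
        assert len(report.removed_snps) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        gm = simulate_genotypes(rng.uniform(0.2, 0.5, 10), 250, rng)
        gm.calls[rng.random(gm.calls.shape) < 0.03] = MISSING_CALL
        once, _ = run_qc(gm)
        twice, rep2 = run_qc(once)
        assert twice == once
        assert rep2.removed_snps == {} and rep2.removed_individuals == []

    def test_filters_never_alter_surviving_calls(self):
        rng = np.random.default_rng(3)
        gm = simulate_genotypes(rng.uniform(0.2, 0.5, 10), 250, rng)
        gm.calls[rng.random(gm.calls.shape) < 0.05] = MISSING_CALL
        out, _ = run_qc(gm)
        rows = [gm.individual_ids.index(i) for i in out.individual_ids]
        cols = [gm.snp_ids.index(s) for s in out.snp_ids]
        orig = gm.calls[np.ix_(rows, cols)]
        surviving = out.calls != MISSING_CALL
        assert np.array_equal(out.calls[surviving], orig[surviving])

    def test_report_json_counts_match_ids(self, tmp_path):
        rng = np.random.default_rng(4)
        gm = simulate_genotypes(rng.uniform(0.2, 0.5, 8), 100, rng)
        gm.calls[0, :] = MISSING_CALL
        _, report = run_qc(gm)
        import json
        payload = json.loads(report.to_json(tmp_path / "qc.json"))
        for plex, ids in payload["plex_removals"].items():
            assert payload["plex_removal_counts"][plex] == len(ids)


def test_genotype_counts_ignores_missing(tiny_gm):
    assert genotype_counts(tiny_gm, 0) == (1, 1, 1)
    assert genotype_counts(tiny_gm, 1) == (0, 1, 1)
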