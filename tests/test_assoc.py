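import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snpset_generalist import assoc
from snpset_generalist.errors import DegenerateInputError
from snpset_generalist.io import PhenotypeTable
from snpset_generalist.assoc import (AnalysisPlan, associate,
                                     association_table, one_tailed_p,
                                     pearson_r, regress_out_and_associate,
                                     significance_flags)
from snpset_generalist.power import r_to_pct_variance

from oracles import pearson_by_formula


def series(values, name="v"):
    return pd.Series(values, index=[f"i{k}" for k in range(len(values))],
                     name=name, dtype=float)


class TestPearson:
    def test_perfect_linearity(self):
        x = series([1, 2, 3, 4])
        r, n = pearson_r(x, series([3, 5, 7, 9], "y"))
        assert r == pytest.approx(1.0) and n == 4

    def test_orthogonal_vectors(self):
        r, _ = pearson_r(series([1, -1, 1, -1]), series([1, 1, -1, -1], "y"))
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([0.2, 1.4, -0.6, 2.2, 0.9, -1.3, 0.4, 1.8])
        y = np.array([1.1, 2.0, -0.2, 1.7, 0.8, -0.9, 0.1, 2.5])
        r, n = pearson_r(series(x), series(y, "y"))
        assert n == 8
        assert r == pytest.approx(pearson_by_formula(x, y), abs=1e-12)

    def test_pairwise_complete_cases(self):
        x = series([1, 2, np.nan, 4, 5])
        y = series([2, np.nan, 3, 8, 10], "y")
        _, n = pearson_r(x, y)
        assert n == 3

    def test_constant_predictor_degenerates(self):
        with pytest.raises(DegenerateInputError):
            pearson_r(series([1, 1, 1, 1]), series([1, 2, 3, 4], "y"))


class TestOneTailedP:
    def test_zero_correlation_gives_half(self):
        for n in (10, 100, 1000):
            assert one_tailed_p(0.0, n) == pytest.approx(0.5)

    def test_wrong_direction_exceeds_half(self):
        assert one_tailed_p(-0.1, 100) > 0.5

    def test_published_value_consistent_within_rounding(self):
        # a correlation printed as 0.096 at N=1480 carries p ~ 1.0e-4
        p = one_tailed_p(0.096, 1480)
        assert 0.8e-4 < p < 1.3e-4

    def test_perfect_correlation_convention(self):
        assert one_tailed_p(1.0, 50) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    def test_monotone_decreasing_in_r(self, r1, r2):
        lo, hi = sorted((r1, r2))
        if hi - lo < 1e-9:
            return
        assert one_tailed_p(hi, 200) < one_tailed_p(lo, 200)

    def test_monotone_decreasing_in_n_for_positive_r(self):
        ps = [one_tailed_p(0.1, n) for n in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestFlags:
    @pytest.mark.parametrize("p,m,expected", [
        (0.03, 5, (True, False)),
        (0.005, 5, (True, True)),
        (0.2, 5, (False, False)),
        (0.04, 1, (True, True)),
    ])
    def test_nominal_and_bonferroni(self, p, m, expected):
        assert significance_flags(p, m) == expected

    def test_bonferroni_implies_nominal(self):
        for p in np.linspace(0.001, 0.9, 97):
            nominal, bonf = significance_flags(p, 5)
            assert not bonf or nominal


class TestAssociate:
    def test_recovers_planted_effect(self, small_cohort):
        from snpset_generalist.snpset import SnpSetDefinition, build_snpset_scores
        gm, table, truth = small_cohort
        scores = build_snpset_scores(
            gm, SnpSetDefinition("s", tuple(gm.snp_ids)))["score"]
        res = associate(scores, table.measure("focal"))
        # n=600 cohort: sampling half-width ~ 2.2/sqrt(n) ~ 0.09
        assert res.r == pytest.approx(truth.expected_r["focal"], abs=0.09)
        assert res.N == 600

    def test_zero_variance_predictor_degenerates(self):
        with pytest.raises(DegenerateInputError):
            associate(series([2, 2, 2, 2]), series([1, 2, 3, 4], "y"))

    def test_r_squared_consistent_with_power_conversion(self):
        x = series(np.arange(20.0))
        y = series(np.arange(20.0) + np.sin(np.arange(20)), "y")
        r, _ = pearson_r(x, y)
        assert r_to_pct_variance(r) == pytest.approx(100 * r * r, abs=1e-12)


def _cohort_table(n=120, seed=0, missing_half=False):
    rng = np.random.default_rng(seed)
    data = {"sex": rng.integers(0, 2, n),
            "focal": rng.standard_normal(n)}
    for name in ("m1", "m2"):
        data[name] = 0.5 * data["focal"] + rng.standard_normal(n)
    if missing_half:
        m3 = rng.standard_normal(n)
        m3[: n // 2] = np.nan
        data["m3"] = m3
    df = pd.DataFrame(data, index=[f"i{k}" for k in range(n)])
    return PhenotypeTable(df)


class TestAssociationTable:
    def _predictors(self, n=120, seed=1):
        rng = np.random.default_rng(seed)
        return {f"p{j}": series(rng.standard_normal(n), f"p{j}")
                for j in range(5)}

    def test_cardinality_with_rp_row(self):
        table = _cohort_table()
        preds = self._predictors()
        extra = {f"m{j}": table.measure("m1").rename(f"m{j}")
                 for j in range(4, 10)}  # pad to 9 measures
        table.data = table.data.assign(**{k: v for k, v in extra.items()})
        table.measures += list(extra)
        plan = AnalysisPlan(predictors=preds, measures=table.measures,
                            focal_measure="focal")
        out = association_table(plan, table)
        n_measures = len(table.measures)
        assert (out["predictor"] != "r_p").sum() == 5 * n_measures
        assert (out["predictor"] == "r_p").sum() == n_measures

    def test_duplicated_measure_gives_identical_rows(self):
        table = _cohort_table()
        table.data["m1_copy"] = table.data["m1"]
        table.measures.append("m1_copy")
        plan = AnalysisPlan(predictors=self._predictors(),
                            measures=["m1", "m1_copy"])
        out = association_table(plan, table)
        a = out[out.measure == "m1"].drop(columns="measure").reset_index(drop=True)
        b = out[out.measure == "m1_copy"].drop(columns="measure").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_per_cell_n_tracks_missingness(self):
        table = _cohort_table(missing_half=True)
        plan = AnalysisPlan(predictors=self._predictors(),
                            measures=["m1", "m3"])
        out = association_table(plan, table)
        n_full = out[out.measure == "m1"]["N"].iloc[0]
        n_half = out[out.measure == "m3"]["N"].iloc[0]
        assert n_half == n_full / 2

    def test_deterministic(self):
        table = _cohort_table()
        plan = AnalysisPlan(predictors=self._predictors(),
                            measures=["m1", "m2"], focal_measure="focal")
        a = association_table(plan, table)
        b = association_table(plan, table)
        pd.testing.assert_frame_equal(a, b)


class TestRegressOut:
    def test_independent_control_changes_little(self):
        rng = np.random.default_rng(5)
        n = 2000
        pred = series(rng.standard_normal(n), "pred")
        meas = series(0.3 * pred.to_numpy() + rng.standard_normal(n), "m")
        ctrl = series(rng.standard_normal(n), "c")
        plain = associate(pred, meas)
        adj = regress_out_and_associate(pred, meas, [ctrl])
        assert adj.r == pytest.approx(plain.r, abs=0.03)

    def test_control_equal_to_measure_degenerates(self):
        rng = np.random.default_rng(6)
        meas = series(rng.standard_normal(50), "m")
        pred = series(rng.standard_normal(50), "p")
        with pytest.raises(DegenerateInputError):
            regress_out_and_associate(pred, meas, [meas.rename("ctrl")])

    def test_shared_path_control_attenuates_but_preserves_sign(self, small_cohort):
        from snpset_generalist.snpset import SnpSetDefinition, build_snpset_scores
        gm, table, _ = small_cohort
        scores = build_snpset_scores(
            gm, SnpSetDefinition("s", tuple(gm.snp_ids)))["score"]
        plain = associate(scores, table.measure("focal"))
        adj = regress_out_and_associate(scores, table.measure("focal"),
                                        [table.measure("half")])
        assert 0 < adj.r < plain.r


class TestNullUniformity:
    def test_null_pvalues_uniform(self):
        """Under no association the one-tailed p-values are uniform."""
        rng = np.random.default_rng(7)
        n, reps = 100, 1000
        ps = np.empty(reps)
        for k in range(reps):
            x = series(rng.standard_normal(n))
            y = series(rng.standard_normal(n), "y")
            r, m = pearson_r(x, y)
            ps[k] = one_tailed_p(r, m)
        from scipy.stats import kstest
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.05
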