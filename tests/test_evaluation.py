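import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accelharm.evaluation import (classification_from_table, cohort_mean_sd,
                                  correlation_regression,
                                  cutoff_classification, daily_median_curves,
                                  participant_correlations, total_ac_errors)
from accelharm.harmonization import fit_mapping

from conftest import make_participant


@pytest.fixture(scope="module")
def identity_model():
    rng = np.random.default_rng(0)
    ac = rng.uniform(1, 6000, 20_000)
    return fit_mapping(ac, ac.copy(), measure_name="mims")


def _cohort_from_arrays(ac_arrays, measure_arrays, measure="mims", **demo):
    cohort = []
    for i, (ac, mv) in enumerate(zip(ac_arrays, measure_arrays)):
        p = make_participant(ac, participant=f"C{i}",
                             valid=np.ones(len(ac), bool), **{measure: mv},
                             **demo)
        cohort.append(p)
    return cohort


class TestCorrelations:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        ac = rng.uniform(0, 5000, 1440)
        cohort = _cohort_from_arrays([ac], [2 * ac + 3])
        rec = participant_correlations(cohort, "mims")
        assert rec["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_relation_gives_minus_one(self):
        rng = np.random.default_rng(2)
        ac = rng.uniform(0, 5000, 1440)
        rec = participant_correlations(_cohort_from_arrays([ac], [-ac]), "mims")
        assert rec["r"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_only_valid_minutes_enter(self):
        ac = np.arange(1440, dtype=float)
        mv = ac.copy()
        mv[:720] = -ac[:720]  # invalid half is anticorrelated
        valid = np.zeros(1440, bool)
        valid[720:] = True
        p = make_participant(ac, valid=valid, mims=mv)
        rec = participant_correlations([p], "mims")
        assert rec["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_yields_missing(self):
        rec = participant_correlations(
            _cohort_from_arrays([np.ones(1440)], [np.arange(1440.0)]), "mims")
        assert np.isnan(rec["r"].iloc[0])

    def test_bivariate_normal_monte_carlo(self):
        rng = np.random.default_rng(3)
        rho, n = 0.9, 5_000
        cov = [[1, rho], [rho, 1]]
        rs = []
        for _ in range(20):
            z = rng.multivariate_normal([0, 0], cov, n)
            rs.append(np.corrcoef(z[:, 0], z[:, 1])[0, 1])
            ac = 1000 + 100 * z[:, 0]
            mv = 10 + z[:, 1]
            rec = participant_correlations(
                _cohort_from_arrays([ac[:1440 * 3]], [mv[:1440 * 3]]), "mims")
            rs[-1] = rec["r"].iloc[0]
        assert abs(np.mean(rs) - rho) < 0.02


class TestCorrelationRegression:
    @staticmethod
    def _records(n=500, seed=4, beta_age=-0.0005, noise=0.01):
        rng = np.random.default_rng(seed)
        age = rng.uniform(40, 90, n)
        bmi = rng.normal(27, 5, n)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        r = 0.95 + beta_age * age + 0.0002 * bmi \
            - 0.004 * (sex == "male") + rng.normal(0, noise, n)
        return pd.DataFrame({"participant": [f"P{i}" for i in range(n)],
                             "r": r, "age": age, "bmi": bmi, "sex": sex})

    def test_identical_correlations_give_exact_intercept(self):
        rec = self._records()
        rec["r"] = 0.9
        out = correlation_regression(rec, adjusted=False)
        assert out["estimate"].iloc[0] == pytest.approx(0.9, abs=1e-12)
        assert out["se"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_known_coefficients_recovered_within_2se(self):
        out = correlation_regression(self._records(), adjusted=True)
        est = out.set_index("term")
        for term, truth in [("const", 0.95), ("age", -0.0005),
                            ("bmi", 0.0002), ("sex_male", -0.004)]:
            assert abs(est.loc[term, "estimate"] - truth) < \
                2 * est.loc[term, "se"] + 1e-12

    def test_adjusted_output_has_demographic_terms(self):
        out = correlation_regression(self._records(), adjusted=True)
        assert list(out["term"]) == ["const", "age", "bmi", "sex_male"]
        assert {"estimate", "se", "p_value", "significant"} <= set(out.columns)

    def test_collinear_covariates_raise(self):
        rec = self._records()
        rec["bmi"] = rec["age"] * 2  # exactly collinear
        with pytest.raises(ValueError, match="collinear"):
            correlation_regression(rec, adjusted=True)

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            correlation_regression(self._records(n=5))


class TestTotalAcErrors:
    def test_perfect_mapping_gives_zero_errors(self, identity_model):
        rng = np.random.default_rng(5)
        ac = rng.uniform(10, 5000, 2 * 1440)
        err = total_ac_errors(_cohort_from_arrays([ac], [ac.copy()]),
                              identity_model, "mims")
        for col in ("mpe", "mape", "mdpe", "mdape"):
            assert abs(err[col].iloc[0]) < 0.5  # grid interpolation only

    def test_constant_inflation_gives_equal_mpe_mape(self, identity_model):
        rng = np.random.default_rng(6)
        ac = rng.uniform(10, 5000, 3 * 1440)
        err = total_ac_errors(_cohort_from_arrays([ac], [1.1 * ac]),
                              identity_model, "mims")
        assert err["mpe"].iloc[0] == pytest.approx(10.0, abs=0.6)
        assert err["mape"].iloc[0] == pytest.approx(err["mpe"].iloc[0], abs=1e-9)

    def test_symmetric_errors_cancel_in_mpe_only(self, identity_model):
        rng = np.random.default_rng(7)
        day = rng.uniform(10, 4000, 1440)
        ac = np.r_[day, day]
        mv = np.r_[0.9 * day, 1.1 * day]  # −10% day then +10% day
        err = total_ac_errors(_cohort_from_arrays([ac], [mv]),
                              identity_model, "mims")
        assert err["mpe"].iloc[0] == pytest.approx(0.0, abs=0.6)
        assert err["mape"].iloc[0] == pytest.approx(10.0, abs=0.6)
        assert err["mdape"].iloc[0] == pytest.approx(10.0, abs=0.6)

    def test_zero_total_days_excluded(self, identity_model):
        day = np.r_[np.zeros(1440), np.full(1440, 100.0)]
        err = total_ac_errors(_cohort_from_arrays([day], [day.copy()]),
                              identity_model, "mims")
        assert err["n_days"].iloc[0] == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_mape_bounds_mpe_on_random_cohorts(self, identity_model, seed):
        # property: MAPE >= |MPE| and MdAPE >= |MdPE| for any error pattern
        rng = np.random.default_rng(seed)
        n_days = int(rng.integers(2, 6))
        ac = rng.uniform(10, 5000, n_days * 1440)
        mv = ac * rng.uniform(0.5, 1.5, n_days * 1440)
        err = total_ac_errors(_cohort_from_arrays([ac], [mv]),
                              identity_model, "mims")
        assert err["mape"].iloc[0] >= abs(err["mpe"].iloc[0]) - 1e-9
        assert err["mdape"].iloc[0] >= abs(err["mdpe"].iloc[0]) - 1e-9


class TestClassification:
    def test_perfect_mapping_is_perfect(self, identity_model):
        rng = np.random.default_rng(8)
        ac = rng.uniform(10, 5000, 1440)
        rep = cutoff_classification(_cohort_from_arrays([ac], [ac.copy()]),
                                    identity_model, "mims", 1853.0)
        assert rep["accuracy"].iloc[0] == 1.0
        assert rep["sensitivity"].iloc[0] == 1.0
        assert rep["specificity"].iloc[0] == 1.0

    def test_contingency_table_arithmetic(self):
        stats = classification_from_table(tp=40, fn=10, fp=5, tn=45)
        assert stats["accuracy"] == pytest.approx(0.85)
        assert stats["sensitivity"] == pytest.approx(0.80)
        assert stats["specificity"] == pytest.approx(0.90)

    def test_all_zero_prediction(self, identity_model):
        rng = np.random.default_rng(9)
        ac = rng.uniform(10, 5000, 1440)
        rep = cutoff_classification(_cohort_from_arrays([ac], [np.zeros(1440)]),
                                    identity_model, "mims", 1853.0)
        assert rep["specificity"].iloc[0] == 1.0
        assert rep["sensitivity"].iloc[0] == 0.0

    def test_no_positive_minutes_gives_missing_sensitivity(self, identity_model):
        ac = np.full(1440, 10.0)
        rep = cutoff_classification(_cohort_from_arrays([ac], [ac.copy()]),
                                    identity_model, "mims", 1853.0)
        assert np.isnan(rep["sensitivity"].iloc[0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_accuracy_identity_on_enumerated_tables(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        s = classification_from_table(tp, fn, fp, tn)
        pos, neg = tp + fn, fp + tn
        if pos and neg:
            assert s["accuracy"] == pytest.approx(
                (s["sensitivity"] * pos + s["specificity"] * neg) / (pos + neg))


class TestMedianCurves:
    def test_identical_mapping_gives_zero_curve_mape(self, identity_model):
        rng = np.random.default_rng(10)
        cohort = []
        for i, age in enumerate([50, 65, 70, 80]):
            ac = rng.uniform(10, 4000, 2 * 1440)
            cohort += _cohort_from_arrays([ac], [ac.copy()], age=float(age))
            cohort[-1].participant_id = f"M{i}"
        curves, mape = daily_median_curves(cohort, identity_model, "mims")
        assert mape == pytest.approx(0.0, abs=0.3)

    def test_constant_scaling_gives_scaled_mape(self, identity_model):
        rng = np.random.default_rng(11)
        ac = rng.uniform(10, 4000, 3 * 1440)
        cohort = _cohort_from_arrays([ac], [1.05 * ac], age=70.0)
        curves, mape = daily_median_curves(cohort, identity_model, "mims")
        assert mape == pytest.approx(5.0, abs=0.5)

    def test_unsmoothed_median_matches_generative_median(self):
        rng = np.random.default_rng(12)
        t = np.arange(1440)
        base = 100 + 50 * np.sin(2 * np.pi * t / 1440)
        cohort = []
        for i in range(6):
            age = 50.0 if i < 3 else 80.0
            noise = rng.normal(0, 5, 4 * 1440)
            ac = np.tile(base, 4) + noise
            p = make_participant(np.maximum(ac, 0), participant=f"G{i}",
                                 valid=np.ones(4 * 1440, bool), age=age)
            cohort.append(p)
        curves, _ = daily_median_curves(cohort, smooth=False)
        for grp in curves["group"].unique():
            c = curves[curves["group"] == grp]["ac_curve"].to_numpy()
            if len(c):
                assert np.abs(c - base).max() < 15  # Monte-Carlo error bound

    def test_empty_groups_are_excluded(self, identity_model):
        rng = np.random.default_rng(13)
        ac = rng.uniform(10, 4000, 1440)
        cohort = _cohort_from_arrays([ac], [ac.copy()], age=50.0)
        curves, _ = daily_median_curves(cohort, identity_model, "mims")
        assert set(curves["group"]) == {"<60"}


def test_cohort_mean_sd_aggregation():
    df = pd.DataFrame({"mape": [1.0, 2.0, 3.0]})
    agg = cohort_mean_sd(df, ["mape"])
    assert agg.loc["mape", "mean"] == pytest.approx(2.0)
    assert agg.loc["mape", "sd"] == pytest.approx(1.0)
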