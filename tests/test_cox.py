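import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icasurv import synthetic
from icasurv.cox import (
    fit_cox,
    hazard_ratio_ci,
    log_partial_likelihood,
    run_model_suite,
    significant_factors,
    wald_test,
)


def worked_example():
    """4 subjects: events at t=1 (x=1), t=2 (x=0); censored at 3 (x=1), 4 (x=0)."""
    x = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]})
    return x, [1.0, 2.0, 3.0, 4.0], [True, True, False, False]


def brute_force_beta(x, time, event, grid=None):
    """Grid-search maximiser of the written-out Breslow partial likelihood."""
    x = np.asarray(x, dtype=float)
    time, event = np.asarray(time, float), np.asarray(event, bool)
    if grid is None:
        grid = np.linspace(-5, 5, 200_001)
    lls = np.zeros_like(grid)
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        # log-sum-exp over the risk set, vectorised across the beta grid
        lls += grid * x[i] - np.log(
            np.exp(np.outer(grid, x[risk])).sum(axis=1)
        )
    best = int(np.argmax(lls))
    return grid[best], lls[best]


class TestFitCox:
    def test_worked_example_beta_closed_form(self):
        x, t, e = worked_example()
        res = fit_cox(x, t, e)
        assert res.beta["x"] == pytest.approx(0.5 * np.log(2), abs=1e-6)
        assert res.summary["hr"].iloc[0] == pytest.approx(np.sqrt(2), abs=1e-5)
        assert res.converged

    def test_worked_example_null_loglik(self):
        x, t, e = worked_example()
        res = fit_cox(x, t, e)
        assert res.loglik_null == pytest.approx(-(np.log(4) + np.log(3)), abs=1e-12)
        assert log_partial_likelihood([0.0], x, t, e) == pytest.approx(
            res.loglik_null
        )

    def test_grid_search_oracle_single_covariate(self):
        x, t, e = worked_example()
        b_grid, _ = brute_force_beta(x["x"], t, e)
        res = fit_cox(x, t, e)
        assert res.beta["x"] == pytest.approx(b_grid, abs=1e-3)

    def test_grid_search_oracle_random_small_data(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            n = int(rng.integers(5, 9))
            x = pd.DataFrame({"x": rng.standard_normal(n)})
            t = rng.exponential(1.0, n) + 0.01
            e = rng.random(n) < 0.7
            if e.sum() < 2:
                continue
            res = fit_cox(x, t, e)
            if not res.converged:
                continue  # separation in a tiny sample
            b_grid, _ = brute_force_beta(x["x"], t, e)
            assert res.beta["x"] == pytest.approx(b_grid, abs=1e-3)

    def test_duplication_invariance_breslow(self):
        x, t, e = worked_example()
        res1 = fit_cox(x, t, e)
        x2 = pd.concat([x, x], ignore_index=True)
        res2 = fit_cox(x2, t + t, e + e)
        assert res2.beta["x"] == pytest.approx(res1.beta["x"], abs=1e-8)

    def test_matches_lifelines_on_moderate_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 150
        x = pd.DataFrame(
            {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        eta = 0.5 * x["a"] - 0.3 * x["b"]
        t = rng.exponential(1.0, n) / np.exp(eta)
        e = t < np.quantile(t, 0.7)
        t = np.minimum(t, np.quantile(t, 0.7))
        res = fit_cox(x, t + 1e-6, e, tie_method="breslow")
        df = x.assign(t=t + 1e-6, e=e.astype(int))
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(res.beta.to_numpy(), cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(
            res.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-4
        )

    def test_efron_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 120
        x = pd.DataFrame({"a": rng.standard_normal(n)})
        t = np.ceil(rng.exponential(5.0, n) * np.exp(-0.4 * x["a"]))
        t = np.clip(t, 1, 12)
        e = rng.random(n) < 0.8
        res = fit_cox(x, t, e, tie_method="efron")
        df = x.assign(t=t, e=e.astype(int))
        cph = CoxPHFitter().fit(df, "t", "e")  # lifelines default is Efron
        assert res.beta["a"] == pytest.approx(cph.params_["a"], abs=1e-5)
        assert res.se["a"] == pytest.approx(cph.standard_errors_["a"], abs=1e-5)

    def test_constant_covariate_named(self):
        x = pd.DataFrame({"ok": [1.0, 2.0, 3.0, 4.0], "flat": [2.0] * 4})
        with pytest.raises(ValueError, match="flat"):
            fit_cox(x, [1, 2, 3, 4], [True, True, False, False])

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(20)
        x = pd.DataFrame({"a": a, "twice_a": 2 * a})
        with pytest.raises(ValueError, match="twice_a"):
            fit_cox(x, np.arange(1, 21), [True] * 10 + [False] * 10)

    def test_no_events_rejected(self):
        x = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(x, [1, 2], [False, False])

    def test_monotone_likelihood_flagged(self):
        # perfect risk separation: the high-x subjects all convert first
        x = pd.DataFrame({"x": [3.0, 2.8, 2.5, 0.1, 0.0, 0.2]})
        t = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        e = [True, True, True, False, False, False]
        with pytest.warns(RuntimeWarning, match="separation|convergence"):
            res = fit_cox(x, t, e)
        assert not res.converged
        assert res.message

    @settings(max_examples=15, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_covariate_scaling_property(self, scale):
        rng = np.random.default_rng(7)
        n = 60
        x = pd.DataFrame({"x": rng.standard_normal(n)})
        t = rng.exponential(1.0, n) * np.exp(-0.5 * x["x"]) + 0.01
        e = rng.random(n) < 0.8
        res1 = fit_cox(x, t, e)
        res2 = fit_cox(x * scale, t, e)
        assert res2.beta["x"] == pytest.approx(res1.beta["x"] / scale, rel=1e-5)
        assert res2.summary["z"].iloc[0] == pytest.approx(
            res1.summary["z"].iloc[0], rel=1e-5
        )
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-8)


class TestHazardRatioCI:
    def test_hr_is_exp_beta_paper_row(self):
        hr, _, _ = hazard_ratio_ci(-7.550, 1.535)
        assert f"{hr:.2e}" == "5.26e-04"

    def test_beta_zero_hr_one(self):
        hr, lo, hi = hazard_ratio_ci(0.0, 1.0)
        assert hr == 1.0
        assert lo < 1.0 < hi

    def test_paper_ci_upper_bound(self):
        _, _, hi = hazard_ratio_ci(-9.398, 2.598, level=0.95)
        assert f"{hi:.1e}" == "1.3e-02"

    def test_ci_brackets_hr(self, rng):
        for _ in range(20):
            b, s = rng.normal(0, 3), rng.uniform(0.1, 3)
            hr, lo, hi = hazard_ratio_ci(b, s)
            assert lo < hr < hi
            assert hr == pytest.approx(np.exp(b))

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            hazard_ratio_ci(1.0, 0.0)
        with pytest.raises(ValueError):
            hazard_ratio_ci(1.0, 1.0, level=1.5)


class TestWald:
    def test_beta_zero_p_one(self):
        z, p = wald_test(0.0, 2.0)
        assert z == 0.0 and p == 1.0

    def test_z_1959964_p_005(self):
        _, p = wald_test(1.95996, 1.0)
        assert p == pytest.approx(0.05, abs=1e-5)

    def test_extreme_z_against_normal_cdf_oracle(self):
        from scipy import stats

        _, p = wald_test(5.0, 1.0)
        assert p == pytest.approx(2 * stats.norm.sf(5.0), rel=1e-12)


class TestSignificantFactors:
    def _result(self, pvals):
        from icasurv.cox import CoxModelResult

        summary = pd.DataFrame(
            {
                "covariate": [f"c{i}" for i in range(len(pvals))],
                "beta": 0.0,
                "se": 1.0,
                "z": 0.0,
                "p": pvals,
                "hr": 1.0,
                "ci_low": 0.5,
                "ci_high": 2.0,
            }
        )
        return CoxModelResult(
            summary=summary, loglik=0.0, loglik_null=0.0, n_iter=1,
            converged=True, n_subjects=10, n_events=5, tie_method="breslow",
        )

    def test_none_significant(self):
        assert significant_factors(self._result([0.2, 0.9])) == []

    def test_alpha_one_keeps_all(self):
        assert significant_factors(self._result([0.2, 0.9]), alpha=1.0) == [
            "c0",
            "c1",
        ]

    def test_mixed_vector(self):
        assert significant_factors(self._result([0.04, 0.06])) == ["c0"]


@pytest.fixture(scope="module")
def planted_tables():
    """Survival cohort where one 'MRI' feature drives the hazard."""
    rng = np.random.default_rng(15)
    n = 400
    mri = pd.DataFrame(
        {
            "structural_IC_00": rng.normal(4, 1, n),
            "structural_IC_01": rng.normal(4, 1, n),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    pet = pd.DataFrame(
        {"metabolic_IC_00": rng.normal(4, 1, n)}, index=mri.index
    )
    clinical = synthetic.sample_clinical(
        synthetic.ClinicalParams(), n, rng
    ).set_index(mri.index)
    eta = -1.2 * (mri["structural_IC_00"] - 4) + 0.1 * (
        clinical["adas_cog"] - clinical["adas_cog"].mean()
    )
    t = rng.exponential(1.0, n) / (0.05 * np.exp(eta))
    event = t <= 36
    surv = pd.DataFrame(
        {"time_months": np.where(event, np.maximum(t, 0.1), 36.0), "event": event},
        index=mri.index,
    )
    return mri, pet, clinical, surv


class TestModelSuite:
    def test_chaining_carries_the_driving_feature(self, planted_tables):
        mri, pet, clinical, surv = planted_tables
        suite = run_model_suite(mri, pet, clinical, surv)
        assert "structural_IC_00" in suite.carried_forward["two_modality"]
        assert suite.models["two_modality"] is not None
        comp = suite.carried_forward["comprehensive"]
        assert "structural_IC_00" in comp
        assert "adas_cog" in comp

    def test_clinical_beta_recovery_large_n(self, small_atlas):
        _, clinical, surv, truth = synthetic.simulate_survival_cohort(
            small_atlas,
            true_beta={"adas_cog": 0.10},
            n=2000,
            seed=21,
        )
        res = fit_cox(
            clinical.set_index("subject_id")[["adas_cog"]].astype(float),
            surv["time_months"],
            surv["event"],
        )
        assert abs(res.beta["adas_cog"] - 0.10) < 3 * res.se["adas_cog"]

    def test_identical_modality_tables_raise_collinear(self, planted_tables):
        mri, _, clinical, surv = planted_tables
        pet_dup = mri[["structural_IC_00"]].rename(
            columns={"structural_IC_00": "metabolic_IC_00"}
        )
        with pytest.raises(ValueError, match="collinear"):
            run_model_suite(mri, pet_dup, clinical, surv)

    def test_empty_stage_skipped_with_reason(self, planted_tables):
        mri, pet, clinical, surv = planted_tables
        empty = pd.DataFrame(index=mri.index)
        suite = run_model_suite(empty, empty, clinical, surv)
        assert suite.models["structural"] is None
        assert "no covariates" in suite.skipped["structural"]
        assert suite.models["clinical"] is not None
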