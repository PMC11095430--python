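"""Mixed-model trajectories: fitter correctness, AICc, stepwise entry, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest

from clarc import (
    LmeSpec,
    SimConfig,
    aicc,
    bootstrap_ci,
    fit_lme,
    generate,
    select_reference,
    stepwise_covariates,
)
from clarc.simulate import BaselineMix, CovariateEffects
from clarc.trajectories import build_model_frame

ZERO_EFFECTS = CovariateEffects(0, 0, 0, 0, 0)


@pytest.fixture(scope="module")
def recovery_cohort():
    """Known world: common slope 1.5 CL/yr, APOE x time = 1.0, null sex effect."""
    cfg = SimConfig(seed=11, n_subjects=400, arc_poly=(1.5, 0.0, 0.0),
                    effects=CovariateEffects(0, 0, 1.0, 0, 0))
    cohort, truth = generate(cfg)
    return cohort, truth, select_reference(cohort)


# --------------------------------------------------------------------------
# AICc
# --------------------------------------------------------------------------

def test_aicc_closed_form():
    # independent arithmetic: 90 + 10 + 60/44
    assert aicc(-45.0, 5, 50) == pytest.approx(90 + 10 + 60 / 44, abs=1e-12)
    assert aicc(-45.0, 0, 50) == pytest.approx(90.0, abs=1e-12)


@pytest.mark.parametrize("k", [1, 3, 10])
def test_aicc_exceeds_aic(k):
    ll, n = -100.0, 80
    assert aicc(ll, k, n) > -2 * ll + 2 * k


def test_aicc_undefined_for_tiny_n():
    with pytest.raises(ValueError):
        aicc(-10.0, 5, 6)


# --------------------------------------------------------------------------
# Fitter vs statsmodels MixedLM (independent route)
# --------------------------------------------------------------------------

def test_lmm_matches_statsmodels(recovery_cohort):
    import statsmodels.api as sm
    from clarc.trajectories import _design
    cohort, _, groups = recovery_cohort
    df = build_model_frame(cohort, groups)
    spec = LmeSpec()
    sub, endog, exog, exog_re = _design(spec, df)
    fit = fit_lme(spec, cohort, groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = sm.MixedLM(endog, exog.to_numpy(), groups=sub["subject_id"].to_numpy(),
                       exog_re=exog_re)
        ref = m.fit(reml=False, method="powell", maxiter=500)
        ref = m.fit(reml=False, method="lbfgs", start_params=ref.params_object)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
    np.testing.assert_allclose(fit.estimates["beta"], ref.fe_params, atol=1e-4)
    np.testing.assert_allclose(fit.estimates["se"], ref.bse_fe, atol=1e-3)
    np.testing.assert_allclose(fit.random_variances["cov_re"],
                               np.asarray(ref.cov_re), rtol=0.01, atol=1e-3)


def test_lmm_reml_matches_statsmodels_loglik(recovery_cohort):
    import statsmodels.api as sm
    from clarc.trajectories import _design
    cohort, _, groups = recovery_cohort
    df = build_model_frame(cohort, groups)
    sub, endog, exog, exog_re = _design(LmeSpec(), df)
    fit = fit_lme(LmeSpec(), cohort, groups, reml=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = sm.MixedLM(endog, exog.to_numpy(), groups=sub["subject_id"].to_numpy(),
                       exog_re=exog_re)
        ref = m.fit(reml=True, method="powell", maxiter=500)
        ref = m.fit(reml=True, method="lbfgs", start_params=ref.params_object)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
    np.testing.assert_allclose(fit.estimates["beta"], ref.fe_params, atol=1e-4)


# --------------------------------------------------------------------------
# Parameter recovery and degenerate data
# --------------------------------------------------------------------------

def test_fit_recovers_known_slope(recovery_cohort):
    cohort, _, groups = recovery_cohort
    spec = LmeSpec().with_terms("apoe_carrier", "apoe_carrier:time")
    fit = fit_lme(spec, cohort, groups)
    est = fit.estimates
    assert est.at["time", "beta"] == pytest.approx(1.5, abs=3 * est.at["time", "se"])
    inter = [t for t in est.index if "apoe" in t and ":time" in t][0]
    assert est.at[inter, "beta"] == pytest.approx(1.0, abs=3 * est.at[inter, "se"])


def test_noise_free_zero_slope_time_coefficient_is_zero():
    cfg = SimConfig(n_subjects=60, seed=5, noise_sd=0.0, vr_flip_prob=0.0,
                    arc_poly=(0.0, 0.0, 0.0), arc_sd_between=0.0,
                    effects=ZERO_EFFECTS,
                    baseline_mix=BaselineMix(weight_normal=1.0, normal_mean=0.0,
                                             normal_sd=3.0, weight_path=0.0))
    cohort, _ = generate(cfg)
    fit = fit_lme(LmeSpec(fixed_terms=("time",),
                          random_structure="common_intercept_slope"), cohort)
    assert abs(fit.estimates.at["time", "beta"]) < 1e-8


def test_rank_deficient_design_raises(recovery_cohort):
    from clarc.trajectories import RankDeficientDesignError, _fit_frame
    cohort, _, groups = recovery_cohort
    df = build_model_frame(cohort, groups)
    df["age0c"] = 0.0  # constant covariate column is aliased with the intercept
    with pytest.raises(RankDeficientDesignError):
        _fit_frame(LmeSpec().with_terms("age0"), df)


def test_spec_requires_main_effect_for_interaction():
    with pytest.raises(ValueError, match="main effect"):
        LmeSpec(fixed_terms=("time", "group", "group:time", "apoe_carrier:time"))


# --------------------------------------------------------------------------
# Stepwise covariate entry
# --------------------------------------------------------------------------

def test_stepwise_retains_apoe_interaction_drops_sex(recovery_cohort):
    cohort, _, groups = recovery_cohort
    spec, trail = stepwise_covariates(cohort, groups,
                                      candidate_order=("apoe_carrier", "sex"))
    assert "apoe_carrier:time" in spec.fixed_terms
    assert "sex" not in spec.fixed_terms and "sex:time" not in spec.fixed_terms
    by_term = {r.term: r for r in trail}
    assert by_term["apoe_carrier:time"].retained
    assert not by_term["sex"].retained
    # audit trail records every comparison with AICc and t
    assert {r.term for r in trail} == {"apoe_carrier", "apoe_carrier:time",
                                       "sex", "sex:time"}
    assert all(np.isfinite([r.aicc_before, r.aicc_after, r.t_stat]).all() for r in trail)


# --------------------------------------------------------------------------
# Cluster bootstrap
# --------------------------------------------------------------------------

def test_bootstrap_deterministic_and_shaped(recovery_cohort):
    cohort, _, groups = recovery_cohort
    ci1, draws1 = bootstrap_ci(LmeSpec(), cohort, groups, n_boot=8, seed=42)
    ci2, draws2 = bootstrap_ci(LmeSpec(), cohort, groups, n_boot=8, seed=42)
    pd.testing.assert_frame_equal(ci1, ci2)
    pd.testing.assert_frame_equal(draws1, draws2)
    assert (ci1["ci_low"] <= ci1["ci_high"]).all()
    assert ci1["n_draws"].iloc[0] == 8


def test_bootstrap_near_zero_width_on_zero_noise():
    cfg = SimConfig(n_subjects=80, seed=9, noise_sd=0.0, vr_flip_prob=0.0,
                    arc_poly=(1.0, 0.0, 0.0), arc_sd_between=0.0,
                    effects=ZERO_EFFECTS,
                    baseline_mix=BaselineMix(weight_normal=1.0, normal_mean=0.0,
                                             normal_sd=3.0, weight_path=0.0))
    cohort, _ = generate(cfg)
    spec = LmeSpec(fixed_terms=("time",), random_structure="common_intercept_slope")
    ci, _ = bootstrap_ci(spec, cohort, n_boot=10, seed=0)
    width = ci.at["time", "ci_high"] - ci.at["time", "ci_low"]
    assert width < 1e-6
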