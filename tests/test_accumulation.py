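"""ARC computation, reference selection, normative and GMM thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clarc import (
    GaussianMixtureThreshold,
    NormativeThreshold,
    ReferenceCriteria,
    classify_accumulators,
    compute_arc,
    fit_gmm2,
    gmm_threshold,
    normative_threshold,
    select_reference,
)

from conftest import make_cohort_from_trajectories


# --------------------------------------------------------------------------
# ARC
# --------------------------------------------------------------------------

@pytest.mark.parametrize("points, expected_arc, expected_dt", [
    ([(0.0, 10.0), (2.0, 16.0)], 3.0, 2.0),
    ([(0.0, 5.0), (2.0, 8.0), (5.0, 14.0)], 1.8, 5.0),  # latest follow-up rule
    ([(0.0, 7.0), (1.5, 7.0), (3.0, 7.0)], 0.0, 3.0),
])
def test_compute_arc_arithmetic(points, expected_arc, expected_dt):
    cohort = make_cohort_from_trajectories({"X": points})
    arc = compute_arc(cohort)
    assert arc.at["X", "arc"] == pytest.approx(expected_arc)
    assert arc.at["X", "dt"] == pytest.approx(expected_dt)


def test_compute_arc_max_cl_rule_uses_peak_followup():
    cohort = make_cohort_from_trajectories({"X": [(0.0, 5.0), (2.0, 15.0), (4.0, 9.0)]})
    last = compute_arc(cohort, rule="last")
    peak = compute_arc(cohort, rule="max_cl")
    assert last.at["X", "arc"] == pytest.approx(1.0)
    assert peak.at["X", "arc"] == pytest.approx(5.0)
    assert peak.at["X", "dt"] == pytest.approx(2.0)


def test_compute_arc_invariant_to_row_order(default_cohort):
    cohort, _ = default_cohort
    arc1 = compute_arc(cohort)
    shuffled = cohort.scans.sample(frac=1, random_state=0)
    from clarc import Cohort
    arc2 = compute_arc(Cohort(scans=shuffled, subjects=cohort.subjects))
    pd.testing.assert_frame_equal(arc1, arc2)


def test_compute_arc_excludes_single_scan_subjects():
    cohort = make_cohort_from_trajectories(
        {"X": [(0.0, 1.0), (2.0, 3.0)], "Y": [(0.0, 4.0)]})
    arc = compute_arc(cohort)
    assert list(arc.index) == ["X"]


# --------------------------------------------------------------------------
# Reference selection
# --------------------------------------------------------------------------

def _two_subject_cohort(cl0_a=2.0, csf_a=True):
    trajs = {"A": [(0.0, cl0_a), (2.0, cl0_a + 1)], "B": [(0.0, 30.0), (2.0, 40.0)]}
    vr = {"A": ["neg", "neg"], "B": ["pos", "pos"]}
    subjects = pd.DataFrame({
        "subject_id": ["A", "B"],
        "age0": 65.0, "sex": "F", "apoe4": 0, "education": "compulsory",
        "cdr": 0.0,
        "csf_abeta_neg": pd.array([csf_a, False], dtype="boolean"),
        "csf_ptau_neg": pd.array([csf_a, False], dtype="boolean"),
    })
    return make_cohort_from_trajectories(trajs, vr=vr, subjects=subjects)


def test_select_reference_happy_path():
    labels = select_reference(_two_subject_cohort())
    assert labels["A"] == "reference" and labels["B"] == "exploratory"


def test_select_reference_cl0_bound_is_strict():
    labels = select_reference(_two_subject_cohort(cl0_a=12.0))
    assert labels["A"] == "exploratory"  # 12.0 is not < 12
    labels = select_reference(_two_subject_cohort(cl0_a=11.999))
    assert labels["A"] == "reference"


def test_select_reference_missing_csf_goes_exploratory():
    labels = select_reference(_two_subject_cohort(csf_a=pd.NA))
    assert labels["A"] == "exploratory"


def test_select_reference_csf_only_criteria():
    # no CL bound, no VR requirement: selection on CSF flags alone
    crit = ReferenceCriteria(cl0_max=None, require_vr_neg_all=False)
    cohort = _two_subject_cohort(cl0_a=50.0)
    labels = select_reference(cohort, crit)
    assert labels["A"] == "reference" and labels["B"] == "exploratory"


def test_reference_exploratory_partition(default_cohort):
    cohort, _ = default_cohort
    arc = compute_arc(cohort)
    labels = select_reference(cohort, arc_table=arc)
    assert set(labels.index) == set(arc.index)
    assert set(labels.unique()) <= {"reference", "exploratory"}
    ref = labels[labels == "reference"].index
    assert (arc.loc[ref, "cl0"] < 12).all()


# --------------------------------------------------------------------------
# Normative threshold
# --------------------------------------------------------------------------

def test_normative_constant_input_zero_width_ci():
    est = normative_threshold(np.full(25, 1.7), seed=0)
    assert est.value == pytest.approx(1.7)
    assert est.ci_low == pytest.approx(1.7) and est.ci_high == pytest.approx(1.7)


def test_normative_linear_interpolation_quantile():
    # h = (n-1)p = 9*0.95 = 8.55 -> 4.0 + 0.55*(10.0-4.0) = 7.3
    sample = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 10.0]
    est = normative_threshold(sample, seed=0)
    assert est.value == pytest.approx(7.3)
    # independent oracle: scipy's linear-interpolation quantile
    assert est.value == pytest.approx(
        stats.scoreatpercentile(sample, 95, interpolation_method="fraction"))


def test_normative_recovers_gaussian_quantile():
    rng = np.random.default_rng(2024)
    est = normative_threshold(rng.normal(0, 1, 10_000), seed=1)
    assert 1.58 <= est.value <= 1.71  # analytic 1.6449
    assert est.ci_low <= 1.6449 <= est.ci_high


def test_normative_ci_mean_variant_much_smaller():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 400)
    p95 = normative_threshold(x, seed=0)
    cim = normative_threshold(x, seed=0, method="ci_mean")
    assert cim.method == "normative_ci_mean"
    assert cim.value == pytest.approx(x.mean() + 1.959963985 * x.std(ddof=1) / 20, rel=1e-6)
    assert cim.value < p95.value


def test_normative_requires_two_values():
    with pytest.raises(ValueError):
        normative_threshold([1.0])


def test_normative_estimator_predict_is_strict():
    est = NormativeThreshold(seed=0).fit(np.arange(100.0))
    t = est.threshold_
    assert est.predict([t, t + 1e-9, t - 1e-9]).tolist() == [False, True, False]


# --------------------------------------------------------------------------
# GMM
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def bimodal_sample():
    rng = np.random.default_rng(42)
    return np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])


def test_gmm_recovers_bimodal_components(bimodal_sample):
    fit = fit_gmm2(bimodal_sample, seed=0)
    assert fit.converged
    assert abs(fit.means[0] - 0) < 0.2 and abs(fit.means[1] - 10) < 0.2
    assert abs(fit.sds[0] - 1) < 0.2 and abs(fit.sds[1] - 1) < 0.2
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_gmm_matches_sklearn_mixture(bimodal_sample):
    # independent route: sklearn's EM on the same data
    from sklearn.mixture import GaussianMixture
    ours = fit_gmm2(bimodal_sample, seed=0)
    sk = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(bimodal_sample[:, None])
    order = np.argsort(sk.means_.ravel())
    np.testing.assert_allclose(ours.means, sk.means_.ravel()[order], atol=1e-3)
    np.testing.assert_allclose(ours.sds, np.sqrt(sk.covariances_.ravel())[order], atol=1e-3)
    assert ours.loglik == pytest.approx(sk.score(bimodal_sample[:, None]) * len(bimodal_sample), abs=0.01)


def test_gmm_loglik_trace_monotone(bimodal_sample, default_cohort):
    cohort, _ = default_cohort
    arc = compute_arc(cohort)["arc"].to_numpy()
    for data in (bimodal_sample, arc):
        fit = fit_gmm2(data, seed=3)
        assert (np.diff(fit.loglik_trace) >= -1e-9).all()


def test_gmm_degenerate_input_raises():
    with pytest.raises(ValueError, match="degenerate|identical"):
        fit_gmm2(np.full(50, 2.0))
    with pytest.raises(ValueError, match=">= 10"):
        fit_gmm2(np.arange(5.0))


def test_gmm_threshold_closed_form(bimodal_sample):
    from clarc.accumulation import GmmFit
    fit = GmmFit(weights=np.array([0.5, 0.5]), means=np.array([0.0, 10.0]),
                 sds=np.array([1.0, 1.0]), loglik_trace=np.array([-1.0]),
                 n_iter=1, converged=True)
    assert gmm_threshold(fit, level=0.99).value == pytest.approx(2.3263, abs=1e-4)
    fit.sds = np.array([0.0, 1.0])
    assert gmm_threshold(fit).value == pytest.approx(0.0)


def test_gmm_threshold_on_bimodal_fixture(bimodal_sample):
    est = GaussianMixtureThreshold(seed=0).fit(bimodal_sample)
    assert 2.0 <= est.threshold_ <= 2.7


def test_gmm_threshold_unconverged_requires_force(bimodal_sample):
    fit = fit_gmm2(bimodal_sample, seed=0, max_iter=2)
    if not fit.converged:
        with pytest.raises(ValueError, match="converge"):
            gmm_threshold(fit)
        assert gmm_threshold(fit, force=True).value is not None


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def test_classify_accumulators_strict_boundary():
    arc = pd.DataFrame({"arc": [3.0, 3.0 + 1e-9, 2.0]},
                       index=pd.Index(["A", "B", "C"], name="subject_id"))
    labels = classify_accumulators(arc, 3.0, scope="all")
    assert labels.tolist() == ["non_accumulator", "accumulator", "non_accumulator"]


def test_classify_accumulators_conservation(default_cohort):
    cohort, _ = default_cohort
    arc = compute_arc(cohort)
    groups = select_reference(cohort, arc_table=arc)
    labels = classify_accumulators(arc, 3.0, group_labels=groups)
    assert len(labels) == (groups == "exploratory").sum()
    assert (labels.isin(["accumulator", "non_accumulator"])).all()


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=40),
       st.floats(0.05, 0.95))
def test_normative_percentile_between_min_and_max(values, level):
    est = normative_threshold(values, level=level, n_boot=50, seed=0)
    assert min(values) - 1e-12 <= est.value <= max(values) + 1e-12
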