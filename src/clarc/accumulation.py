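"""Annualized rate of change (ARC) and reliable-accumulation thresholds.

ARC is (CL at the latest follow-up - CL at baseline) / follow-up interval in
years.  "Reliable" accumulation is an ARC exceeding the variability expected
in subjects with no true amyloid change, estimated either as

* the empirical 95th percentile of ARC in a stable reference group
  (:class:`NormativeThreshold`), or
* the 99th percentile of the lower-mean component of a two-Gaussian mixture
  fitted to the whole cohort's ARCs (:class:`GaussianMixtureThreshold`).

Both estimators follow the scikit-learn fit/predict protocol: ``fit`` takes a
1-d array of ARC values, ``predict`` labels new ARCs as accumulators (strict
``>`` at the threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, VrCategory, categorize_vr

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# ARC table and reference-group selection
# --------------------------------------------------------------------------

@dataclass
class ReferenceCriteria:
    """Membership rules for the stable (non-accumulating) reference group.

    Defaults mirror the strictest published rule set: baseline CL < 12
    (strict inequality), every visual read negative, and both CSF amyloid
    and CSF p-tau flagged normal.  Subjects missing a required field are
    assigned to the exploratory group (reference must be high-confidence).
    """

    cl0_max: float | None = 12.0
    require_vr_neg_all: bool = True
    require_csf_amyloid_neg: bool = True
    require_csf_ptau_neg: bool = True

    def __post_init__(self) -> None:
        if self.cl0_max is not None and not np.isfinite(self.cl0_max):
            raise ValueError("cl0_max must be finite or None")


def compute_arc(cohort: Cohort, rule: str = "last") -> pd.DataFrame:
    """Per-subject annualized rate of change.

    Parameters
    ----------
    cohort : validated cohort; subjects with a single scan are excluded
        (logged), as are subjects whose follow-up interval is zero.
    rule : "last" uses the latest follow-up scan; "max_cl" uses the
        follow-up with the highest CL (and its own interval as dt).

    Returns
    -------
    DataFrame indexed by subject_id with columns ``arc`` (CL/year), ``dt``
    (years), ``cl0`` (baseline CL), ``tracer`` and, when computable,
    ``vr_category``.
    """
    if rule not in ("last", "max_cl"):
        raise ValueError(f"unknown ARC rule {rule!r}")
    vr_cats = categorize_vr(cohort)
    records = []
    dropped = []
    for sid, grp in cohort.scans.groupby("subject_id", sort=True):
        grp = grp.sort_values("t_years")
        if len(grp) < 2:
            dropped.append(sid)
            continue
        cl0 = float(grp["centiloid"].iloc[0])
        follow = grp.iloc[1:]
        if rule == "last":
            pick = follow.iloc[-1]
        else:
            pick = follow.loc[follow["centiloid"].idxmax()]
        dt = float(pick["t_years"])
        if dt <= 0:
            log.warning("subject %s has zero follow-up interval; excluded", sid)
            dropped.append(sid)
            continue
        arc = (float(pick["centiloid"]) - cl0) / dt
        cat = vr_cats.get(sid)
        records.append((sid, arc, dt, cl0, grp["tracer"].iloc[0],
                        cat.value if cat is not None else None))
    if dropped:
        log.info("compute_arc: excluded %d subjects without usable follow-up", len(dropped))
    table = pd.DataFrame(records,
                         columns=["subject_id", "arc", "dt", "cl0", "tracer", "vr_category"])
    return table.set_index("subject_id")


def select_reference(cohort: Cohort, criteria: ReferenceCriteria | None = None,
                     arc_table: pd.DataFrame | None = None) -> pd.Series:
    """Label each longitudinal subject ``reference`` or ``exploratory``.

    A subject is reference iff baseline CL < ``cl0_max`` (when set), every
    visual read is negative (when required), and the required CSF flags are
    True.  Missing required information sends a subject to exploratory with
    a warning — never to reference.
    """
    criteria = criteria or ReferenceCriteria()
    if arc_table is None:
        arc_table = compute_arc(cohort)
    subjects = cohort.subjects.set_index("subject_id")
    labels = {}
    n_missing = 0
    vr_by_subject = cohort.scans.groupby("subject_id")["vr"]
    all_vr_neg = vr_by_subject.apply(lambda s: s.notna().all() and (s == "neg").all())
    for sid in arc_table.index:
        ok = True
        if criteria.cl0_max is not None:
            ok = ok and arc_table.at[sid, "cl0"] < criteria.cl0_max
        if ok and criteria.require_vr_neg_all:
            ok = bool(all_vr_neg.get(sid, False))
        if ok and criteria.require_csf_amyloid_neg:
            v = subjects.at[sid, "csf_abeta_neg"]
            if pd.isna(v):
                ok, n_missing = False, n_missing + 1
            else:
                ok = bool(v)
        if ok and criteria.require_csf_ptau_neg:
            v = subjects.at[sid, "csf_ptau_neg"]
            if pd.isna(v):
                ok, n_missing = False, n_missing + 1
            else:
                ok = bool(v)
        labels[sid] = "reference" if ok else "exploratory"
    out = pd.Series(labels, name="group")
    counts = out.value_counts()
    log.info("select_reference: %d reference, %d exploratory (%d missing required fields)",
             counts.get("reference", 0), counts.get("exploratory", 0), n_missing)
    return out


# --------------------------------------------------------------------------
# Threshold estimate container
# --------------------------------------------------------------------------

@dataclass
class ThresholdEstimate:
    """A threshold with its 95% CI, the rule that produced it, diagnostics."""

    value: float
    ci_low: float | None
    ci_high: float | None
    method: str
    n_used: int
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value + 1e-12 and self.value - 1e-12 <= self.ci_high):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket value {self.value}")

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n_used": self.n_used,
            "diagnostics": self.diagnostics,
        }


# --------------------------------------------------------------------------
# Normative (percentile) estimator
# --------------------------------------------------------------------------

class NormativeThreshold(BaseEstimator):
    """Reliable-accumulation threshold from a stable reference group.

    ``method="percentile"`` (default): the empirical quantile at ``level``
    of the reference ARCs, with linear interpolation at h = (n-1)p, plus a
    subject-level bootstrap percentile CI.

    ``method="ci_mean"``: mean + z_{0.975} * sd / sqrt(n), the upper bound
    of the 95% CI of the mean ARC — a much smaller number describing the
    uncertainty of the group mean, not of an individual measurement; kept
    for comparability with that alternative reading of the rule.
    """

    def __init__(self, level: float = 0.95, method: str = "percentile",
                 n_boot: int = 1000, seed: int = 0):
        self.level = level
        self.method = method
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None) -> "NormativeThreshold":
        arcs = np.asarray(X, dtype=float).ravel()
        if arcs.size < 2:
            raise ValueError("need at least 2 reference ARC values")
        if arcs.size < 20:
            log.warning("normative threshold on only %d reference subjects", arcs.size)
        if self.method not in ("percentile", "ci_mean"):
            raise ValueError(f"unknown method {self.method!r}")
        rng = np.random.default_rng(self.seed)
        n = arcs.size
        if self.method == "percentile":
            value = float(np.quantile(arcs, self.level))  # linear interpolation, h=(n-1)p
            boots = np.quantile(
                arcs[rng.integers(0, n, size=(self.n_boot, n))], self.level, axis=1)
            ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
            # percentile bootstrap of an extreme quantile can sit entirely to
            # one side of the point estimate in small samples; widen to bracket
            ci = (min(ci[0], value), max(ci[1], value))
            method_name = "normative_p95" if abs(self.level - 0.95) < 1e-12 else \
                f"normative_p{int(round(self.level * 100))}"
        else:
            z = stats.norm.ppf(0.5 + self.level / 2)
            mean, sd = float(arcs.mean()), float(arcs.std(ddof=1))
            value = mean + z * sd / np.sqrt(n)
            boot_means = arcs[rng.integers(0, n, size=(self.n_boot, n))]
            boots = boot_means.mean(axis=1) + z * boot_means.std(ddof=1, axis=1) / np.sqrt(n)
            ci = (float(min(np.quantile(boots, 0.025), value)),
                  float(max(np.quantile(boots, 0.975), value)))
            method_name = "normative_ci_mean"
        self.threshold_ = float(value)
        self.ci_ = ci
        self.n_features_in_ = 1
        self.estimate_ = ThresholdEstimate(
            value=self.threshold_, ci_low=ci[0], ci_high=ci[1],
            method=method_name, n_used=n,
            diagnostics={"mean": float(arcs.mean()), "sd": float(arcs.std(ddof=1)), "n": n},
        )
        return self

    def predict(self, X) -> np.ndarray:
        """True where ARC strictly exceeds the fitted threshold."""
        check_is_fitted(self, "threshold_")
        return np.asarray(X, dtype=float).ravel() > self.threshold_


def normative_threshold(ref_arcs, level: float = 0.95, n_boot: int = 1000,
                        seed: int = 0, method: str = "percentile") -> ThresholdEstimate:
    """Functional wrapper around :class:`NormativeThreshold`."""
    est = NormativeThreshold(level=level, method=method, n_boot=n_boot, seed=seed)
    return est.fit(ref_arcs).estimate_


# --------------------------------------------------------------------------
# Two-component Gaussian mixture (EM) estimator
# --------------------------------------------------------------------------

@dataclass
class GmmFit:
    """A fitted univariate 2-component Gaussian mixture."""

    weights: np.ndarray  # (2,), sums to 1
    means: np.ndarray    # (2,), sorted ascending
    sds: np.ndarray      # (2,), >= floor
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _em_loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> tuple:
    comp = np.stack([stats.norm.logpdf(x, mu[k], sd[k]) + np.log(w[k]) for k in (0, 1)])
    m = comp.max(axis=0)
    lse = m + np.log(np.exp(comp - m).sum(axis=0))
    resp = np.exp(comp - lse)
    return float(lse.sum()), resp


def fit_gmm2(arcs, seed: int = 0, n_init: int = 10, tol: float = 1e-8,
             max_iter: int = 500) -> GmmFit:
    """Maximum-likelihood univariate 2-Gaussian mixture via EM.

    Best of ``n_init`` initializations; each initialization places the two
    means at a random pair of spread quantiles of the data (fixed sub-seeds
    from ``seed``).  The per-iteration log-likelihood is recorded and is
    non-decreasing (an EM guarantee, asserted in tests).  Component
    standard deviations are floored at 1e-4 times the data SD to prevent
    collapse onto single points.
    """
    x = np.asarray(arcs, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need >= 10 observations for a 2-component mixture, got {x.size}")
    data_sd = x.std(ddof=1)
    if data_sd == 0:
        raise ValueError("degenerate data: all observations identical")
    floor = 1e-4 * data_sd

    best: GmmFit | None = None
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2 ** 31 - 1, size=n_init)
    for s in sub_seeds:
        rng = np.random.default_rng(int(s))
        qlo, qhi = sorted(rng.uniform(0.05, 0.95, size=2))
        if qhi - qlo < 0.2:
            qlo, qhi = max(0.0, qlo - 0.1), min(1.0, qhi + 0.1)
        mu = np.array([np.quantile(x, qlo), np.quantile(x, qhi)])
        sd = np.array([data_sd, data_sd]) * 0.5
        w = np.array([0.5, 0.5])
        trace = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            ll, resp = _em_loglik(x, w, mu, sd)
            trace.append(ll)
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-12)
            w = nk / x.size
            mu = (resp * x).sum(axis=1) / nk
            var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
            sd = np.maximum(np.sqrt(var), floor)
            if ll - prev < tol and it > 1:
                converged = True
                break
            prev = ll
        ll, _ = _em_loglik(x, w, mu, sd)
        trace.append(ll)
        order = np.argsort(mu)
        fit = GmmFit(weights=w[order], means=mu[order], sds=sd[order],
                     loglik_trace=np.asarray(trace), n_iter=it, converged=converged)
        # a component collapsing onto a handful of points (weight ~ 0, sd at
        # the floor) yields a spurious likelihood spike; such runs are not
        # admissible mixture solutions and are skipped unless nothing else
        # converged
        collapsed = fit.weights.min() < max(0.01, 2.0 / x.size) or fit.sds.min() <= floor * 1.001
        if not collapsed and (best is None or fit.loglik > best.loglik):
            best = fit
        if collapsed and best is None:
            fallback = fit
    if best is None:
        best = fallback
    if not best.converged:
        log.warning("GMM EM did not converge within %d iterations", max_iter)
    return best


def gmm_threshold(fit: GmmFit, level: float = 0.99, force: bool = False) -> ThresholdEstimate:
    """Threshold = quantile at ``level`` of the lower-mean mixture component.

    value = mu_1 + z_level * sigma_1.  Raises on an unconverged fit unless
    ``force`` is True.
    """
    if not fit.converged and not force:
        raise ValueError("GMM fit did not converge; pass force=True to override")
    z = stats.norm.ppf(level)
    value = float(fit.means[0] + z * fit.sds[0])
    return ThresholdEstimate(
        value=value, ci_low=None, ci_high=None,
        method=f"gmm_p{int(round(level * 100))}", n_used=int(fit.n_iter),
        diagnostics={
            "weights": fit.weights.tolist(),
            "means": fit.means.tolist(),
            "sds": fit.sds.tolist(),
            "loglik": fit.loglik,
            "converged": fit.converged,
        },
    )


class GaussianMixtureThreshold(BaseEstimator):
    """sklearn-style wrapper: fit a 2-Gaussian mixture to ARCs and threshold
    at the ``level`` quantile of the lower component."""

    def __init__(self, level: float = 0.99, seed: int = 0, n_init: int = 10,
                 tol: float = 1e-8, max_iter: int = 500):
        self.level = level
        self.seed = seed
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "GaussianMixtureThreshold":
        self.gmm_ = fit_gmm2(X, seed=self.seed, n_init=self.n_init,
                             tol=self.tol, max_iter=self.max_iter)
        self.estimate_ = gmm_threshold(self.gmm_, level=self.level, force=True)
        self.threshold_ = self.estimate_.value
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return np.asarray(X, dtype=float).ravel() > self.threshold_


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_accumulators(arc_table: pd.DataFrame, threshold: ThresholdEstimate | float,
                          group_labels: pd.Series | None = None,
                          scope: str = "exploratory") -> pd.Series:
    """Label subjects accumulator / non_accumulator (strict ``arc > value``).

    Applied to the exploratory group by default; pass ``scope="all"`` for the
    whole ARC table.
    """
    value = threshold.value if isinstance(threshold, ThresholdEstimate) else float(threshold)
    if not np.isfinite(value):
        raise ValueError("threshold must be finite")
    table = arc_table
    if scope == "exploratory":
        if group_labels is None:
            raise ValueError("group labels required for scope='exploratory'")
        table = arc_table.loc[group_labels.reindex(arc_table.index) == "exploratory"]
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    labels = np.where(table["arc"] > value, "accumulator", "non_accumulator")
    return pd.Series(labels, index=table.index, name="accumulator_status")
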