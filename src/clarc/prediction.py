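"""Baseline-CL threshold that best predicts future amyloid accumulation.

Precision-recall analysis over candidate thresholds (the sorted unique
baseline CL values; predicted positive iff CL >= t), maximizing the F1 score,
optionally under a minimum-precision / minimum-recall / minimum-specificity
constraint.  Bootstrap resampling both optimizes the threshold (point
estimate = mean of 500 per-resample optima) and derives its 95% CI (the
2.5th/97.5th percentiles of thresholds re-optimized on 1000 further
resamples, each validated out-of-bag).

Precision-recall is preferred to ROC here because accumulators are the
minority class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import derive_seed
from .accumulation import ThresholdEstimate
from .cohort import Cohort

log = logging.getLogger(__name__)

CURVE_COLUMNS = ["threshold", "tp", "fp", "tn", "fn",
                 "precision", "recall", "specificity", "f1"]

_CONSTRAINT_METRICS = ("precision", "recall", "specificity")


class SingleClassError(ValueError):
    """Both classes are needed for a PR analysis."""


def pr_curve(cl0, labels) -> pd.DataFrame:
    """Exact precision-recall curve over all candidate thresholds.

    Candidates are the sorted unique baseline CL values; a subject is
    predicted positive iff its baseline CL >= threshold.  F1 is defined as 0
    when precision + recall = 0.
    """
    x = np.asarray(cl0, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if x.shape != y.shape:
        raise ValueError("cl0 and labels must have equal length")
    _check_both_classes(y)
    return _pr_curve_arrays(x, y)


def _check_both_classes(y: np.ndarray) -> None:
    if not y.any():
        raise SingleClassError("no positive (accumulator) labels present")
    if y.all():
        raise SingleClassError("no negative (non-accumulator) labels present")


def _pr_curve_arrays(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    thresholds = np.unique(xs)
    n = xs.size
    total_pos = int(ys.sum())
    cum_pos = np.concatenate([[0], np.cumsum(ys)])
    idx = np.searchsorted(xs, thresholds, side="left")
    tp = total_pos - cum_pos[idx]
    pred_pos = n - idx
    fp = pred_pos - tp
    fn = total_pos - tp
    tn = (n - total_pos) - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 0.0)
        recall = tp / total_pos
        specificity = tn / (n - total_pos)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame({
        "threshold": thresholds,
        "tp": tp.astype(int), "fp": fp.astype(int),
        "tn": tn.astype(int), "fn": fn.astype(int),
        "precision": precision, "recall": recall,
        "specificity": specificity, "f1": f1,
    })


def _best_threshold(curve: pd.DataFrame,
                    constraint: tuple[str, float] | None) -> tuple[float, float] | None:
    """(threshold, f1) maximizing F1 under the constraint; ties -> smallest
    threshold; None when the constraint is infeasible."""
    f1 = curve["f1"].to_numpy()
    if constraint is not None:
        metric, min_value = constraint
        feasible = curve[metric].to_numpy() >= min_value
        if not feasible.any():
            return None
        f1 = np.where(feasible, f1, -np.inf)
    i = int(np.argmax(f1))  # thresholds ascending -> first max is the smallest
    return float(curve["threshold"].iloc[i]), float(curve["f1"].iloc[i])


def best_threshold(cl0, labels, constraint: tuple[str, float] | None = None) -> ThresholdEstimate:
    """Brute-force full-sample optimum (no bootstrap); the oracle route."""
    curve = pr_curve(cl0, labels)
    _validate_constraint(constraint)
    res = _best_threshold(curve, constraint)
    if res is None:
        raise ValueError(f"constraint {constraint} infeasible on the full sample")
    t, f1 = res
    row = curve.loc[curve["threshold"] == t].iloc[0]
    return ThresholdEstimate(
        value=t, ci_low=None, ci_high=None, method="pr_f1" if constraint is None else "pr_constrained",
        n_used=len(cl0),
        diagnostics={"f1": f1, "precision": float(row["precision"]),
                     "recall": float(row["recall"]), "specificity": float(row["specificity"])},
    )


def _validate_constraint(constraint) -> None:
    if constraint is None:
        return
    metric, min_value = constraint
    if metric not in _CONSTRAINT_METRICS:
        raise ValueError(f"constraint metric must be one of {_CONSTRAINT_METRICS}, got {metric!r}")
    if not 0.0 <= float(min_value) <= 1.0:
        raise ValueError("constraint minimum must be in [0, 1]")


@dataclass
class PrResult:
    """Full output of a bootstrap-optimized precision-recall analysis."""

    curve: pd.DataFrame
    optimal: ThresholdEstimate
    scenario: str
    opt_thresholds: np.ndarray   # per-resample optima (point-estimate stage)
    boot_thresholds: np.ndarray  # per-resample optima (CI stage)
    oob_f1: np.ndarray           # out-of-bag F1 per CI resample (nan if no OOB class mix)
    feasibility: float = 1.0
    full_sample: ThresholdEstimate | None = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "optimal": self.optimal.to_dict(),
            "full_sample": self.full_sample.to_dict() if self.full_sample else None,
            "feasibility": self.feasibility,
            "curve": self.curve.to_dict(orient="list"),
            "opt_thresholds": self.opt_thresholds.tolist(),
            "boot_thresholds": self.boot_thresholds.tolist(),
            "oob_f1": [None if np.isnan(v) else float(v) for v in self.oob_f1],
        }


class PrecisionRecallThreshold(BaseEstimator, ClassifierMixin):
    """Bootstrap-optimized baseline-CL cutoff predicting accumulator status.

    Parameters
    ----------
    n_opt : bootstrap resamples used to optimize the point estimate (mean of
        per-resample F1-optimal thresholds; ``agg="median"`` available).
    n_ci : further resamples for the 95% percentile CI, each optimum
        validated on its out-of-bag subjects.
    constraint : optional ("precision"|"recall"|"specificity", minimum).
    seed : governs all resampling; results are deterministic given
        (data, seed, n_opt, n_ci).

    Attributes (after fit)
    ----------------------
    threshold_ : the point estimate (CL).
    ci_ : (low, high) 95% CI.
    curve_ : full-sample PR curve DataFrame.
    result_ : the complete :class:`PrResult`.
    """

    def __init__(self, n_opt: int = 500, n_ci: int = 1000, seed: int = 0,
                 constraint: tuple[str, float] | None = None, agg: str = "mean"):
        self.n_opt = n_opt
        self.n_ci = n_ci
        self.seed = seed
        self.constraint = constraint
        self.agg = agg

    def fit(self, X, y) -> "PrecisionRecallThreshold":
        x = np.asarray(X, dtype=float).ravel()
        lab = np.asarray(y).ravel().astype(bool)
        if x.shape != lab.shape:
            raise ValueError("cl0 and labels must have equal length")
        _check_both_classes(lab)
        _validate_constraint(self.constraint)
        if self.agg not in ("mean", "median"):
            raise ValueError(f"agg must be 'mean' or 'median', got {self.agg!r}")
        n = x.size
        if n < 30:
            log.warning("precision-recall threshold on only %d subjects", n)

        curve = _pr_curve_arrays(x, lab)
        full = _best_threshold(curve, self.constraint)
        rng = np.random.default_rng(self.seed)

        opt_thresholds, n_infeasible = self._resample_optima(x, lab, self.n_opt, rng)
        n_eff = self.n_opt - int(np.isnan(opt_thresholds).sum())
        feasibility = 1.0 - n_infeasible / max(self.n_opt, 1)
        if feasibility < 0.5:
            raise ValueError(
                f"constraint {self.constraint} infeasible in "
                f"{100 * (1 - feasibility):.0f}% of optimization resamples")
        point = (np.nanmean if self.agg == "mean" else np.nanmedian)(opt_thresholds)

        boot_thresholds, _ = self._resample_optima(x, lab, self.n_ci, rng, oob=True)
        self._oob_f1 = self._last_oob_f1
        valid = boot_thresholds[~np.isnan(boot_thresholds)]
        ci = (float(np.quantile(valid, 0.025)), float(np.quantile(valid, 0.975)))
        ci = (min(ci[0], point), max(ci[1], point))

        scenario = "f1" if self.constraint is None else \
            f"min_{self.constraint[0]}_{self.constraint[1]:g}"
        estimate = ThresholdEstimate(
            value=float(point), ci_low=ci[0], ci_high=ci[1],
            method="pr_f1" if self.constraint is None else "pr_constrained",
            n_used=n,
            diagnostics={"n_opt_effective": n_eff, "feasibility": feasibility,
                         "agg": self.agg,
                         "full_sample_threshold": None if full is None else full[0]},
        )
        full_est = None
        if full is not None:
            full_est = best_threshold(x, lab, self.constraint)
        self.result_ = PrResult(
            curve=curve, optimal=estimate, scenario=scenario,
            opt_thresholds=opt_thresholds, boot_thresholds=boot_thresholds,
            oob_f1=self._oob_f1, feasibility=feasibility, full_sample=full_est,
        )
        self.threshold_ = estimate.value
        self.ci_ = ci
        self.curve_ = curve
        self.classes_ = np.array([False, True])
        return self

    def _resample_optima(self, x, lab, n_rep, rng, oob: bool = False):
        n = x.size
        out = np.full(n_rep, np.nan)
        oob_f1 = np.full(n_rep, np.nan)
        n_infeasible = 0
        for b in range(n_rep):
            idx = rng.integers(0, n, size=n)
            yb = lab[idx]
            if yb.all() or not yb.any():
                continue  # single-class resample: no optimum defined
            curve = _pr_curve_arrays(x[idx], yb)
            res = _best_threshold(curve, self.constraint)
            if res is None:
                n_infeasible += 1
                continue
            out[b] = res[0]
            if oob:
                mask = np.ones(n, dtype=bool)
                mask[np.unique(idx)] = False
                if mask.any() and lab[mask].any() and not lab[mask].all():
                    pred = x[mask] >= res[0]
                    tp = int((pred & lab[mask]).sum())
                    prec = tp / max(int(pred.sum()), 1)
                    rec = tp / int(lab[mask].sum())
                    oob_f1[b] = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        self._last_oob_f1 = oob_f1
        return out, n_infeasible

    def predict(self, X) -> np.ndarray:
        """Predicted accumulator status: baseline CL >= threshold (inclusive)."""
        check_is_fitted(self, "threshold_")
        return np.asarray(X, dtype=float).ravel() >= self.threshold_


def optimize_threshold(cl0, labels, n_opt: int = 500, n_ci: int = 1000, seed: int = 0,
                       constraint: tuple[str, float] | None = None,
                       agg: str = "mean") -> PrResult:
    """Functional wrapper around :class:`PrecisionRecallThreshold`."""
    est = PrecisionRecallThreshold(n_opt=n_opt, n_ci=n_ci, seed=seed,
                                   constraint=constraint, agg=agg)
    return est.fit(cl0, labels).result_


STRATA = ("vr_baseline_neg_only", "tracer", "apoe_carrier", "education")


def stratified_thresholds(cohort: Cohort, labels: pd.Series, strata: str,
                          n_opt: int = 500, n_ci: int = 1000, seed: int = 0,
                          constraint: tuple[str, float] | None = None) -> dict:
    """Run the PR threshold optimization independently within strata.

    ``labels`` is a boolean accumulator flag indexed by subject_id.  Strata
    lacking one of the two classes are reported as None (not estimable), not
    errors.  Each stratum gets a deterministic sub-seed derived from ``seed``
    and the stratum name.
    """
    if strata not in STRATA:
        raise ValueError(f"unknown stratum scheme {strata!r}; choose from {STRATA}")
    baseline = cohort.scans[cohort.scans["t_years"] == 0].set_index("subject_id")
    subjects = cohort.subjects.set_index("subject_id")
    ids = labels.index

    if strata == "vr_baseline_neg_only":
        members = {"vr_baseline_neg": ids[baseline.loc[ids, "vr"] == "neg"]}
    elif strata == "tracer":
        members = {tr: ids[baseline.loc[ids, "tracer"] == tr]
                   for tr in sorted(baseline.loc[ids, "tracer"].unique())}
    elif strata == "apoe_carrier":
        apoe = subjects.loc[ids, "apoe4"]
        members = {"carrier": ids[(apoe > 0).fillna(False).to_numpy(dtype=bool)],
                   "non_carrier": ids[(apoe == 0).fillna(False).to_numpy(dtype=bool)]}
    else:
        edu = subjects.loc[ids, "education"]
        members = {lvl: ids[(edu == lvl).to_numpy()] for lvl in
                   ("compulsory", "upper_secondary", "post_secondary")}

    out: dict[str, PrResult | None] = {}
    for name, sub_ids in members.items():
        y = labels.loc[sub_ids].to_numpy(dtype=bool)
        if len(sub_ids) == 0 or y.all() or not y.any():
            log.info("stratum %s not estimable (single class or empty)", name)
            out[name] = None
            continue
        x = baseline.loc[sub_ids, "centiloid"].to_numpy(dtype=float)
        out[name] = optimize_threshold(
            x, y, n_opt=n_opt, n_ci=n_ci,
            seed=derive_seed(seed, "stratum", name), constraint=constraint)
    return out
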