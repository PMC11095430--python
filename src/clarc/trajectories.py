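"""Linear mixed-effects modeling of Centiloid trajectories.

The base model regresses CL on time (years from baseline), group
(reference / exploratory) and their interaction, with random intercepts and
slopes per subject (unstructured covariance).  The reference group's random
slope is masked (its slope-variance design column is zeroed) so the model
allows random intercepts only there, in one joint fit.  Covariates are
entered in a fixed order (baseline age, APOE-e4 carriership, tracer, sex,
education) and retained when they lower the small-sample-corrected Akaike
criterion (AICc) and are significant; interactions with time are tested
separately.  Confidence intervals come from a cluster bootstrap that
resamples whole subjects with their scans intact.

Fitting machinery is the vectorised profiled-likelihood solver in
:mod:`clarc._lmm` (cross-checked against statsmodels MixedLM in the test
suite); this module owns the model specification, the group-specific random
structure, the AICc-based entry procedure and the bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from ._lmm import fit_lmm

from .cohort import Cohort, categorize_vr

log = logging.getLogger(__name__)

BASE_TERMS = ("time", "group", "group:time")
COVARIATE_ORDER = ("age0", "apoe_carrier", "tracer", "sex", "education")

_TERM_PATSY = {
    "time": "time",
    "group": "C(group, Treatment('reference'))",
    "age0": "age0c",
    "apoe_carrier": "apoe_carrier",
    "tracer": "C(tracer)",
    "sex": "C(sex)",
    "education": "C(education, Treatment('compulsory'))",
    "vr_category": "C(vr_category, Treatment('stable_neg'))",
    "cog_status": "C(cog_status, Treatment('unimpaired'))",
}

_TERM_COLUMNS = {
    "time": ["time"], "group": ["group"], "age0": ["age0c"],
    "apoe_carrier": ["apoe_carrier"], "tracer": ["tracer"], "sex": ["sex"],
    "education": ["education"], "vr_category": ["vr_category"],
    "cog_status": ["cog_status"],
}

AGE_CENTER = 65.0  # years; baseline age is centred here


class RankDeficientDesignError(ValueError):
    pass


@dataclass
class LmeSpec:
    """A mixed-model specification: ordered fixed terms + random structure.

    ``random_structure`` is either ``study_intercept_slope__ref_intercept``
    (random intercept + slope for the exploratory group, intercept only for
    the reference group) or ``common_intercept_slope``.
    """

    fixed_terms: tuple[str, ...] = BASE_TERMS
    random_structure: str = "study_intercept_slope__ref_intercept"

    def __post_init__(self) -> None:
        self.fixed_terms = tuple(self.fixed_terms)
        known = set(_TERM_PATSY)
        for term in self.fixed_terms:
            base = term.split(":")[0] if term != "time" else "time"
            if term.endswith(":time"):
                main = term[: -len(":time")]
                if main not in known:
                    raise ValueError(f"unknown term {term!r}")
                if main not in self.fixed_terms:
                    raise ValueError(f"interaction {term!r} requires main effect {main!r}")
            elif term not in known:
                raise ValueError(f"unknown term {term!r}")
        if self.random_structure not in ("study_intercept_slope__ref_intercept",
                                         "common_intercept_slope"):
            raise ValueError(f"unknown random structure {self.random_structure!r}")

    def with_terms(self, *terms: str) -> "LmeSpec":
        new = list(self.fixed_terms)
        for t in terms:
            if t not in new:
                new.append(t)
        return replace(self, fixed_terms=tuple(new))

    def formula_rhs(self) -> str:
        parts = []
        for term in self.fixed_terms:
            if term.endswith(":time") :
                main = term[: -len(":time")]
                parts.append(f"{_TERM_PATSY[main]}:time")
            else:
                parts.append(_TERM_PATSY[term])
        return " + ".join(parts) if parts else "1"

    def required_columns(self) -> set[str]:
        cols = {"cl", "time", "subject_id"}
        for term in self.fixed_terms:
            main = term[: -len(":time")] if term.endswith(":time") else term
            cols.update(_TERM_COLUMNS[main])
        return cols


@dataclass
class TrajectoryFit:
    """Estimates, random-effect variances, fit statistics, optional bootstrap."""

    estimates: pd.DataFrame  # index term, columns beta se t_stat p ci_low ci_high
    random_variances: dict
    loglik: float
    aicc: float
    n_obs: int
    n_subjects: int
    converged: bool
    spec: LmeSpec
    boot: pd.DataFrame | None = None  # resampled fixed effects, one row per draw
    boot_ci: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.reset_index().to_dict(orient="list"),
            "random_variances": self.random_variances,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "fixed_terms": list(self.spec.fixed_terms),
            "random_structure": self.spec.random_structure,
            "boot_ci": None if self.boot_ci is None else self.boot_ci.reset_index().to_dict(orient="list"),
        }


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Corrected Akaike information criterion, -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n_obs <= k_params + 1:
        raise ValueError(f"AICc undefined for n={n_obs} <= k+1={k_params + 1}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


def build_model_frame(cohort: Cohort, groups: pd.Series | None = None,
                      exclude_reverters: bool = True) -> pd.DataFrame:
    """Long-format analysis frame: one row per scan with subject covariates.

    ``groups`` is the reference/exploratory labeling from
    :func:`clarc.accumulation.select_reference`; rows of unlabeled subjects
    are dropped.  VR reverters (positive baseline, later negative) are
    excluded from the VR-category factor when ``exclude_reverters``.
    """
    scans = cohort.scans
    subj = cohort.subjects.set_index("subject_id")
    df = scans.rename(columns={"t_years": "time", "centiloid": "cl"}).copy()
    df["age0c"] = subj.loc[df["subject_id"], "age0"].to_numpy() - AGE_CENTER
    apoe = subj.loc[df["subject_id"], "apoe4"]
    df["apoe_carrier"] = np.where(apoe.isna(), np.nan, (apoe > 0).astype(float))
    df["sex"] = subj.loc[df["subject_id"], "sex"].to_numpy()
    df["education"] = subj.loc[df["subject_id"], "education"].to_numpy()
    cdr = subj.loc[df["subject_id"], "cdr"]
    df["cog_status"] = np.where(cdr.isna(), None,
                                np.where(cdr >= 0.5, "impaired", "unimpaired"))
    cats = categorize_vr(cohort)
    df["vr_category"] = [cats[s].value if s in cats else None for s in df["subject_id"]]
    if exclude_reverters:
        df.loc[df["vr_category"] == "converter_neg", "vr_category"] = None
    if groups is not None:
        df["group"] = groups.reindex(df["subject_id"]).to_numpy()
        df = df[df["group"].notna()]
    else:
        df["group"] = "exploratory"
    return df.reset_index(drop=True)


def _design(spec: LmeSpec, df: pd.DataFrame):
    used = spec.required_columns()
    sub = df.dropna(subset=[c for c in used if c in df.columns])
    n_dropped = len(df) - len(sub)
    if n_dropped:
        log.info("fit_lme: dropped %d rows with missing covariates (complete case)", n_dropped)
    exog = patsy.dmatrix("1 + " + spec.formula_rhs(), sub, return_type="dataframe")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {exog.shape[1]} columns: {list(exog.columns)}")
    endog = sub["cl"].to_numpy(dtype=float)
    if spec.random_structure == "study_intercept_slope__ref_intercept":
        slope_col = sub["time"].to_numpy(dtype=float) * (sub["group"].to_numpy() != "reference")
    else:
        slope_col = sub["time"].to_numpy(dtype=float)
    exog_re = np.column_stack([np.ones(len(sub)), slope_col])
    return sub, endog, exog, exog_re


def _fit_frame(spec: LmeSpec, df: pd.DataFrame, reml: bool = False,
               start: tuple | None = None) -> TrajectoryFit:
    sub, endog, exog, exog_re = _design(spec, df)
    start_cov, start_scale = start if start is not None else (None, None)
    res = fit_lmm(endog, exog.to_numpy(), sub["subject_id"].to_numpy(), exog_re,
                  reml=reml, start_cov=start_cov, start_scale=start_scale)
    k_fe = exog.shape[1]
    q = exog_re.shape[1]
    k = k_fe + q * (q + 1) // 2 + 1  # fixed + unstructured RE covariance + residual
    names = list(exog.columns)
    beta = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(tstat))
    z = stats.norm.ppf(0.975)
    est = pd.DataFrame({
        "beta": beta, "se": se, "t_stat": tstat, "p": pvals,
        "ci_low": beta - z * se, "ci_high": beta + z * se,
    }, index=pd.Index(names, name="term"))
    n_obs = len(sub)
    fit = TrajectoryFit(
        estimates=est,
        random_variances={
            "cov_re": np.asarray(res.cov_re).tolist(),
            "residual_var": float(res.scale),
        },
        loglik=float(res.llf),
        aicc=aicc(float(res.llf), k, n_obs),
        n_obs=n_obs,
        n_subjects=int(sub["subject_id"].nunique()),
        converged=bool(res.converged),
        spec=spec,
    )
    fit._warm = (res.cov_re, res.scale)  # warm start for bootstrap refits
    if not fit.converged:
        log.warning("mixed-model optimizer did not converge for terms %s", spec.fixed_terms)
    return fit


def fit_lme(spec: LmeSpec, cohort: Cohort, groups: pd.Series | None = None,
            reml: bool = False, frame: pd.DataFrame | None = None) -> TrajectoryFit:
    """Fit the mixed model defined by ``spec``.

    Use ``reml=False`` (maximum likelihood) when comparing AICc across fixed
    structures and ``reml=True`` for final reported estimates.
    """
    df = frame if frame is not None else build_model_frame(cohort, groups)
    return _fit_frame(spec, df, reml=reml)


def _term_columns(term: str, fitted_names: list[str]) -> list[str]:
    """Design-matrix columns generated by a spec term."""
    main = term[: -len(":time")] if term.endswith(":time") else term
    token = _TERM_PATSY[main]
    cols = []
    for name in fitted_names:
        is_inter = ":time" in name or name.startswith("time:") or ":" in name and "time" in name.split(":")
        has_token = name == token or name.startswith(token + "[") or token + "[" in name or name.split(":")[0] == token
        if term == "time":
            if name == "time":
                cols.append(name)
        elif term.endswith(":time"):
            parts = name.split(":")
            if len(parts) == 2 and "time" in parts:
                other = parts[0] if parts[1] == "time" else parts[1]
                if other == token or other.startswith(token + "["):
                    cols.append(name)
        else:
            if ":" not in name and (name == token or name.startswith(token + "[")):
                cols.append(name)
    return cols


@dataclass
class StepRecord:
    term: str
    aicc_before: float
    aicc_after: float
    t_stat: float
    p_value: float
    retained: bool


def stepwise_covariates(cohort: Cohort, groups: pd.Series | None = None,
                        base_spec: LmeSpec | None = None,
                        candidate_order: tuple[str, ...] = COVARIATE_ORDER,
                        alpha: float = 0.05,
                        frame: pd.DataFrame | None = None) -> tuple[LmeSpec, list[StepRecord]]:
    """Ordered covariate entry: AICc improvement AND significance to retain.

    Each candidate's main effect is tested first; its interaction with time
    is then tested separately on top of the main effect (the main effect is
    kept whenever its interaction is retained, preserving hierarchy).  All
    comparisons use maximum likelihood.  Returns the final spec and an audit
    trail of every comparison.
    """
    df = frame if frame is not None else build_model_frame(cohort, groups)
    spec = base_spec or LmeSpec()
    crit = stats.norm.ppf(1 - alpha / 2)
    current_fit = _fit_frame(spec, df, reml=False)
    trail: list[StepRecord] = []

    def test_term(cur_spec: LmeSpec, cur_aicc: float, term: str):
        cand_spec = cur_spec.with_terms(*_with_hierarchy(cur_spec, term))
        fit = _fit_frame(cand_spec, df, reml=False)
        cols = _term_columns(term, list(fit.estimates.index))
        tmax = float(fit.estimates.loc[cols, "t_stat"].abs().max()) if cols else 0.0
        pmin = float(fit.estimates.loc[cols, "p"].min()) if cols else 1.0
        retained = fit.aicc < cur_aicc and abs(tmax) > crit
        trail.append(StepRecord(term, cur_aicc, fit.aicc, tmax, pmin, retained))
        return cand_spec, fit, retained

    for cand in candidate_order:
        spec_main, fit_main, keep_main = test_term(spec, current_fit.aicc, cand)
        base_for_inter = spec_main
        base_aicc = fit_main.aicc
        inter = f"{cand}:time"
        spec_inter, fit_inter, keep_inter = test_term(base_for_inter, base_aicc, inter)
        if keep_inter:
            spec, current_fit = spec_inter, fit_inter
        elif keep_main:
            spec, current_fit = spec_main, fit_main
        # else: candidate dropped entirely, spec unchanged
    return spec, trail


def _with_hierarchy(spec: LmeSpec, term: str) -> tuple[str, ...]:
    if term.endswith(":time"):
        main = term[: -len(":time")]
        if main not in spec.fixed_terms:
            return (main, term)
    return (term,)


class BootstrapFailureError(RuntimeError):
    pass


def bootstrap_ci(spec: LmeSpec, cohort: Cohort, groups: pd.Series | None = None,
                 n_boot: int = 1000, seed: int = 0, reml: bool = True,
                 frame: pd.DataFrame | None = None,
                 max_fail_frac: float = 0.10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-bootstrap percentile CIs for the fixed effects.

    Whole subjects (with all their scans) are resampled with replacement;
    the model is refit per draw.  Failed or unconverged refits are skipped
    and counted; more than ``max_fail_frac`` failures is an error.

    Returns (ci, draws): ``ci`` indexed by term with columns ci_low/ci_high
    and the number of successful draws; ``draws`` is the raw matrix.
    """
    df = frame if frame is not None else build_model_frame(cohort, groups)
    full = _fit_frame(spec, df, reml=reml)
    terms = list(full.estimates.index)
    rng = np.random.default_rng(seed)
    ids = df["subject_id"].unique()
    blocks = {sid: g for sid, g in df.groupby("subject_id")}
    rows: list[np.ndarray] = []
    n_failed = 0
    for b in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for j, sid in enumerate(chosen):
            blk = blocks[sid].copy()
            blk["subject_id"] = f"B{j:06d}"
            parts.append(blk)
        bdf = pd.concat(parts, ignore_index=True)
        try:
            fit = _fit_frame(spec, bdf, reml=reml,
                             start=getattr(full, "_warm", None))
        except Exception:
            n_failed += 1
            continue
        if list(fit.estimates.index) != terms:
            n_failed += 1  # factor level lost in the resample
            continue
        rows.append(fit.estimates["beta"].to_numpy())
    if n_boot and n_failed / n_boot > max_fail_frac:
        raise BootstrapFailureError(
            f"{n_failed}/{n_boot} bootstrap refits failed (> {max_fail_frac:.0%})")
    if n_failed:
        log.info("bootstrap_ci: skipped %d failed refits", n_failed)
    draws = pd.DataFrame(rows, columns=terms)
    ci = pd.DataFrame({
        "ci_low": draws.quantile(0.025),
        "ci_high": draws.quantile(0.975),
        "n_draws": len(draws),
    })
    ci.index.name = "term"
    return ci, draws


def fit_with_bootstrap(spec: LmeSpec, cohort: Cohort, groups: pd.Series | None = None,
                       n_boot: int = 1000, seed: int = 0, reml: bool = True,
                       frame: pd.DataFrame | None = None) -> TrajectoryFit:
    """REML fit plus cluster-bootstrap CIs attached to the result."""
    df = frame if frame is not None else build_model_frame(cohort, groups)
    fit = _fit_frame(spec, df, reml=reml)
    ci, draws = bootstrap_ci(spec, cohort, groups, n_boot=n_boot, seed=seed,
                             reml=reml, frame=df)
    fit.boot = draws
    fit.boot_ci = ci
    return fit
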