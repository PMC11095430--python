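"""Seeded generator of synthetic longitudinal Centiloid cohorts.

Stands in for restricted multi-centre amyloid-PET natural-history data.  The
default configuration reproduces the marginal structure of a pre-dementia
cohort of 750 adults: a baseline Centiloid (CL) distribution mixing a
near-zero amyloid-negative component with a right-skewed pathological one,
an annualized rate of change (ARC) coupled quadratically to baseline CL,
per-scan measurement noise, threshold-plus-error visual reads (producing a
realistic ~1.6% of positive-to-negative "reverters"), CSF normality flags
anti-correlated with latent amyloid, and APOE-e4 / education / tracer
covariate effects on level and slope.

A hidden truth table (latent baseline CL and true slope per subject) is
returned alongside the observable cohort for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the field."""


@dataclass
class BaselineMix:
    """Two-component latent baseline CL distribution.

    Near-zero component: Normal(mean, sd) — amyloid-negative individuals
    (defaults match a stable reference population, 2.4 +/- 5.7 CL).
    Pathological component: shift + LogNormal(log_mean, log_sd) — heavy right
    tail with support above ~10 CL.  Default parameters solve the moment
    equations for a population mean of 14.1 CL, SD 24.6 CL, and 17.5% of
    latent baselines above the 24-CL visual-read threshold.
    """

    weight_normal: float = 0.5790682
    normal_mean: float = 2.4
    normal_sd: float = 5.7
    weight_path: float = 0.4209318
    path_shift: float = 10.0
    path_log_mean: float = 2.4057123
    path_log_sd: float = 1.0952136


@dataclass
class FollowupSchedule:
    """Number and timing of follow-up scans.

    87% of subjects get one follow-up, 13% two; intervals (years from
    baseline) are lognormal around the observed medians (3.0 y for the first
    follow-up, 5.3 y for the second).
    """

    prob_two_followups: float = 0.13
    t1_median: float = 3.0
    t1_log_sd: float = 0.477
    t2_median: float = 5.3
    t2_log_sd: float = 0.028


@dataclass
class CovariateEffects:
    """Covariate effects on baseline CL and on the CL/year slope.

    Baseline effects are mean-centred at generation time so that the
    calibrated population mean of the baseline mixture is preserved.
    ``tracer_offset_cl`` is a measurement-scale offset (FMM reads higher than
    FBB by ~5 CL after adjustment) applied to observed CL only, never to the
    latent trajectory that drives visual reads.
    """

    tracer_offset_cl: float = 5.0
    apoe_baseline_cl: float = 6.0
    apoe_slope_cl_per_yr: float = 1.0
    edu_baseline_cl: float = -1.8  # per education tier (0/1/2)
    edu_slope_cl_per_yr: float = -0.55  # upper/post-secondary vs compulsory


@dataclass
class SimConfig:
    n_subjects: int = 750
    seed: int = 0
    frac_fmm: float = 481 / 750
    frac_female: float = 0.57
    apoe_probs: tuple[float, float, float] = (0.58, 0.37, 0.05)
    apoe_missing_prob: float = 0.02
    education_probs: tuple[float, float, float] = (0.18, 0.29, 0.53)
    age_mean: float = 65.7
    age_sd: float = 7.6
    age_min: float = 50.0
    cdr_pos_prob: float = 0.06
    baseline_mix: BaselineMix = field(default_factory=BaselineMix)
    # quadratic E[ARC | CL0] = a0 + a1*CL0 + a2*CL0^2 (CL/year)
    arc_poly: tuple[float, float, float] = (0.0, 0.15, -0.00125)
    arc_sd_between: float = 1.5
    noise_sd: float = 2.0
    vr_threshold: float = 24.0
    vr_flip_prob: float = 0.02
    followup_schedule: FollowupSchedule = field(default_factory=FollowupSchedule)
    effects: CovariateEffects = field(default_factory=CovariateEffects)
    # CSF normality: P(negative flag) = logistic((csf_midpoint - CL0)/csf_scale)
    csf_midpoint: float = 15.0
    csf_scale: float = 5.0
    csf_missing_prob: float = 0.5

    def validate(self) -> None:
        for name in ("frac_fmm", "frac_female", "vr_flip_prob", "cdr_pos_prob",
                     "apoe_missing_prob", "csf_missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.followup_schedule.prob_two_followups <= 1.0:
            raise SimConfigError("followup_schedule.prob_two_followups must be in [0, 1]")
        for name, v in (("age_sd", self.age_sd),
                        ("baseline_mix.normal_sd", self.baseline_mix.normal_sd),
                        ("baseline_mix.path_log_sd", self.baseline_mix.path_log_sd),
                        ("csf_scale", self.csf_scale)):
            if v <= 0:
                raise SimConfigError(f"{name} must be > 0, got {v}")
        for name, v in (("noise_sd", self.noise_sd), ("arc_sd_between", self.arc_sd_between)):
            if v < 0:
                raise SimConfigError(f"{name} must be >= 0, got {v}")
        probs = np.asarray(self.education_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise SimConfigError("education_probs must be non-negative and sum to 1")
        aprobs = np.asarray(self.apoe_probs, dtype=float)
        if abs(aprobs.sum() - 1.0) > 1e-9 or (aprobs < 0).any():
            raise SimConfigError("apoe_probs must be non-negative and sum to 1")
        w = self.baseline_mix.weight_normal + self.baseline_mix.weight_path
        if abs(w - 1.0) > 1e-6:
            raise SimConfigError(f"baseline_mix weights must sum to 1, got {w}")
        if self.n_subjects < 1:
            raise SimConfigError("n_subjects must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown config fields: {sorted(unknown)}")
        if "baseline_mix" in d and isinstance(d["baseline_mix"], Mapping):
            d["baseline_mix"] = BaselineMix(**d["baseline_mix"])
        if "followup_schedule" in d and isinstance(d["followup_schedule"], Mapping):
            d["followup_schedule"] = FollowupSchedule(**d["followup_schedule"])
        if "effects" in d and isinstance(d["effects"], Mapping):
            d["effects"] = CovariateEffects(**d["effects"])
        for tup in ("apoe_probs", "education_probs", "arc_poly"):
            if tup in d and not isinstance(d[tup], tuple):
                d[tup] = tuple(d[tup])
        return cls(**d)


def generate(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a synthetic cohort plus its hidden truth table.

    Deterministic given ``config.seed``.  The truth table has one row per
    subject with the latent baseline CL (``cl0_true``) and the true linear
    slope (``slope_true``, CL/year) before measurement noise.

    Latent model: CL_true(t) = CL0 + slope * t with
    slope = a0 + a1*CL0 + a2*CL0^2 + covariate effects + N(0, sd_between);
    observed CL = CL_true(t) + tracer offset + N(0, noise_sd) per scan;
    VR per scan = (CL_true(t) > vr_threshold) XOR Bernoulli(flip_prob).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subject_ids = np.array([f"S{i:05d}" for i in range(1, n + 1)])

    # --- covariates -------------------------------------------------------
    age0 = rng.normal(config.age_mean, config.age_sd, size=n)
    while (age0 < config.age_min).any():  # truncate: inclusion is >= 50 y
        bad = age0 < config.age_min
        age0[bad] = rng.normal(config.age_mean, config.age_sd, size=bad.sum())
    sex = np.where(rng.random(n) < config.frac_female, "F", "M")
    apoe4 = rng.choice([0, 1, 2], size=n, p=np.asarray(config.apoe_probs))
    apoe_missing = rng.random(n) < config.apoe_missing_prob
    education_tier = rng.choice([0, 1, 2], size=n, p=np.asarray(config.education_probs))
    cdr = np.where(rng.random(n) < config.cdr_pos_prob, 0.5, 0.0)
    is_fmm = rng.random(n) < config.frac_fmm
    tracer = np.where(is_fmm, "FMM", "FBB")

    # --- latent baseline CL ----------------------------------------------
    mix = config.baseline_mix
    from_path = rng.random(n) < mix.weight_path
    cl0 = rng.normal(mix.normal_mean, mix.normal_sd, size=n)
    n_path = int(from_path.sum())
    cl0[from_path] = mix.path_shift + rng.lognormal(mix.path_log_mean, mix.path_log_sd, size=n_path)

    eff = config.effects
    carrier = (apoe4 > 0).astype(float)
    p_carrier = config.apoe_probs[1] + config.apoe_probs[2]
    mean_tier = float(np.dot([0.0, 1.0, 2.0], config.education_probs))
    # baseline effects centred so that the calibrated mixture mean is kept
    cl0 = cl0 + eff.apoe_baseline_cl * (carrier - p_carrier)
    cl0 = cl0 + eff.edu_baseline_cl * (education_tier - mean_tier)

    # --- slopes -----------------------------------------------------------
    a0, a1, a2 = config.arc_poly
    slope = a0 + a1 * cl0 + a2 * cl0 ** 2
    slope = slope + eff.apoe_slope_cl_per_yr * carrier
    slope = slope + eff.edu_slope_cl_per_yr * (education_tier >= 1).astype(float)
    slope = slope + rng.normal(0.0, config.arc_sd_between, size=n)

    # --- scan schedule ----------------------------------------------------
    sched = config.followup_schedule
    n_follow = np.where(rng.random(n) < sched.prob_two_followups, 2, 1)
    t1 = rng.lognormal(np.log(sched.t1_median), sched.t1_log_sd, size=n)
    t2 = rng.lognormal(np.log(sched.t2_median), sched.t2_log_sd, size=n)
    t2 = np.maximum(t2, t1 + 0.5)

    # --- CSF flags --------------------------------------------------------
    p_neg = 1.0 / (1.0 + np.exp((cl0 - config.csf_midpoint) / config.csf_scale))
    csf_abeta_neg = rng.random(n) < p_neg
    csf_ptau_neg = rng.random(n) < p_neg
    csf_missing = rng.random(n) < config.csf_missing_prob

    # --- scans ------------------------------------------------------------
    rows = []
    tracer_offset = eff.tracer_offset_cl * (is_fmm.astype(float) - config.frac_fmm)
    for i in range(n):
        times = [0.0, round(float(t1[i]), 3)]
        if n_follow[i] == 2:
            times.append(round(float(t2[i]), 3))
        for t in times:
            cl_true = cl0[i] + slope[i] * t
            cl_obs = cl_true + tracer_offset[i] + rng.normal(0.0, config.noise_sd)
            vr_true = cl_true > config.vr_threshold
            flip = rng.random() < config.vr_flip_prob
            vr = vr_true ^ flip
            rows.append((subject_ids[i], t, cl_obs, tracer[i], "pos" if vr else "neg"))

    scans = pd.DataFrame(rows, columns=["subject_id", "t_years", "centiloid", "tracer", "vr"])
    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "age0": np.round(age0, 2),
        "sex": sex,
        "apoe4": pd.array(np.where(apoe_missing, -1, apoe4), dtype="Int64"),
        "education": np.array(["compulsory", "upper_secondary", "post_secondary"])[education_tier],
        "cdr": cdr,
        "csf_abeta_neg": pd.array(csf_abeta_neg, dtype="boolean"),
        "csf_ptau_neg": pd.array(csf_ptau_neg, dtype="boolean"),
    })
    subjects.loc[apoe_missing, "apoe4"] = pd.NA
    subjects.loc[csf_missing, "csf_abeta_neg"] = pd.NA
    subjects.loc[csf_missing, "csf_ptau_neg"] = pd.NA

    truth = pd.DataFrame({
        "subject_id": subject_ids,
        "cl0_true": cl0,
        "slope_true": slope,
    })
    return Cohort(scans=scans, subjects=subjects), truth
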