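"""Longitudinal Centiloid cohort containers, delimited-text IO and validation.

The cohort is long format: one row per PET scan (subject, years since
baseline, Centiloid value, tracer, visual read) plus one row per subject of
baseline covariates.  Time is stored as years from the baseline scan; a
calendar-date converter is provided but dates are never required.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

SCAN_COLUMNS = ["subject_id", "t_years", "centiloid", "tracer", "vr"]
SUBJECT_COLUMNS = [
    "subject_id",
    "age0",
    "sex",
    "apoe4",
    "education",
    "cdr",
    "csf_abeta_neg",
    "csf_ptau_neg",
]

TRACERS = ("FMM", "FBB", "FBP")
SEXES = ("M", "F")
EDUCATION_LEVELS = ("compulsory", "upper_secondary", "post_secondary")
VR_VALUES = ("neg", "pos")


class VrCategory(str, enum.Enum):
    """Visual-read status over time.

    ``stable_neg``   — negative at baseline and every follow-up.
    ``converter_pos``— negative at baseline, positive at some follow-up.
    ``converter_neg``— positive at baseline, negative later (reverters;
                       excluded from converter analyses downstream).
    ``stable_pos``   — positive throughout.
    """

    stable_neg = "stable_neg"
    converter_pos = "converter_pos"
    converter_neg = "converter_neg"
    stable_pos = "stable_pos"


class CohortValidationError(ValueError):
    """A cohort invariant is violated; message lists offending subjects."""


class CohortParseError(ValueError):
    """A file row could not be parsed; message names the line."""


@dataclass
class Cohort:
    """A validated longitudinal cohort.

    Attributes
    ----------
    scans : DataFrame with columns ``subject_id, t_years, centiloid, tracer, vr``
        (``vr`` is "neg"/"pos" or NA), sorted by (subject_id, t_years).
    subjects : DataFrame with one row per subject of baseline covariates.
    """

    scans: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.scans = _normalize_scans(self.scans)
        self.subjects = _normalize_subjects(self.subjects)
        validate_cohort(self.scans, self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def longitudinal_ids(self) -> pd.Index:
        """Subjects with at least two scans."""
        counts = self.scans.groupby("subject_id").size()
        return counts.index[counts >= 2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.scans.equals(other.scans) and self.subjects.equals(other.subjects)


def years_between(start: date, end: date) -> float:
    """Convert a calendar interval to years using 365.25 days/year."""
    return (end - start).days / DAYS_PER_YEAR


def _normalize_scans(scans: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCAN_COLUMNS if c not in scans.columns]
    if missing:
        raise CohortParseError(f"scans table missing columns: {missing}")
    out = scans.loc[:, SCAN_COLUMNS].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["t_years"] = pd.to_numeric(out["t_years"], errors="raise").astype(float)
    out["centiloid"] = pd.to_numeric(out["centiloid"], errors="raise").astype(float)
    out["tracer"] = out["tracer"].astype(str)
    vr = out["vr"].astype("string")
    vr = vr.where(~vr.isin(["NA", "", "nan", "<NA>"]), pd.NA)
    out["vr"] = vr
    out = out.sort_values(["subject_id", "t_years"], kind="mergesort").reset_index(drop=True)
    return out


def _normalize_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise CohortParseError(f"subjects table missing columns: {missing}")
    out = subjects.loc[:, SUBJECT_COLUMNS].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["age0"] = pd.to_numeric(out["age0"], errors="raise").astype(float)
    out["sex"] = out["sex"].astype(str)
    out["apoe4"] = pd.to_numeric(out["apoe4"], errors="coerce").astype("Int64")
    out["education"] = out["education"].astype(str)
    out["cdr"] = pd.to_numeric(out["cdr"], errors="coerce").astype(float)
    for col in ("csf_abeta_neg", "csf_ptau_neg"):
        out[col] = _to_nullable_bool(out[col])
    out = out.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
    return out


def _to_nullable_bool(s: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v) or v in ("", "NA", "nan", "<NA>"):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        sv = str(v).strip().lower()
        if sv in ("true", "1", "1.0"):
            return True
        if sv in ("false", "0", "0.0"):
            return False
        raise CohortParseError(f"cannot parse boolean value {v!r}")

    return s.map(conv).astype("boolean")


def validate_cohort(scans: pd.DataFrame, subjects: pd.DataFrame) -> None:
    """Check all cohort invariants; raise CohortValidationError listing subjects."""
    problems: list[str] = []

    dup_subj = subjects["subject_id"][subjects["subject_id"].duplicated()].unique()
    if len(dup_subj):
        problems.append(f"duplicate subject rows: {sorted(dup_subj)}")

    unknown = sorted(set(scans["subject_id"]) - set(subjects["subject_id"]))
    if unknown:
        problems.append(f"scans reference unknown subjects: {unknown}")

    dup = scans.duplicated(subset=["subject_id", "t_years"], keep=False)
    if dup.any():
        ids = sorted(scans.loc[dup, "subject_id"].unique())
        problems.append(f"duplicate (subject_id, t_years) pairs: {ids}")

    neg_t = scans.loc[scans["t_years"] < 0, "subject_id"].unique()
    if len(neg_t):
        problems.append(f"negative t_years: {sorted(neg_t)}")

    t0 = scans[scans["t_years"] == 0].groupby("subject_id").size()
    no_baseline = sorted(set(scans["subject_id"]) - set(t0.index))
    if no_baseline:
        problems.append(f"subjects without a t=0 baseline scan: {no_baseline}")

    multi_tracer = scans.groupby("subject_id")["tracer"].nunique()
    mixed = sorted(multi_tracer.index[multi_tracer > 1])
    if mixed:
        problems.append(f"mixed-tracer subjects: {mixed}")

    bad_tracer = sorted(scans.loc[~scans["tracer"].isin(TRACERS), "subject_id"].unique())
    if bad_tracer:
        problems.append(f"unknown tracer values for subjects: {bad_tracer}")

    bad_vr = scans["vr"].dropna()
    bad_vr = sorted(scans.loc[scans["vr"].notna() & ~scans["vr"].isin(VR_VALUES), "subject_id"].unique())
    if bad_vr:
        problems.append(f"vr values outside {{neg,pos}}: {bad_vr}")

    bad_sex = sorted(subjects.loc[~subjects["sex"].isin(SEXES), "subject_id"])
    if bad_sex:
        problems.append(f"sex outside {{M,F}}: {bad_sex}")

    bad_edu = sorted(subjects.loc[~subjects["education"].isin(EDUCATION_LEVELS), "subject_id"])
    if bad_edu:
        problems.append(f"education outside enumeration: {bad_edu}")

    bad_apoe = subjects["apoe4"].notna() & ~subjects["apoe4"].isin([0, 1, 2])
    if bad_apoe.any():
        problems.append(f"apoe4 outside {{0,1,2}}: {sorted(subjects.loc[bad_apoe, 'subject_id'])}")

    bad_cdr = subjects["cdr"].notna() & ~subjects["cdr"].isin([0.0, 0.5])
    if bad_cdr.any():
        problems.append(f"cdr outside {{0, 0.5}}: {sorted(subjects.loc[bad_cdr, 'subject_id'])}")

    if problems:
        raise CohortValidationError("; ".join(problems))

    young = subjects.loc[subjects["age0"] < 50, "subject_id"]
    if len(young):
        # inclusion criterion is age > 50; tolerated with a warning
        log.warning("subjects younger than 50 at baseline: %s", sorted(young))


def read_cohort(scans_path, subjects_path, sep: str | None = None) -> Cohort:
    """Read and validate a cohort from two delimited text files.

    Comma is the default delimiter; tab is accepted (autodetected when
    ``sep`` is None).  Missing values are empty fields or ``NA``.
    """
    scans = _read_table(scans_path, sep)
    subjects = _read_table(subjects_path, sep)
    return Cohort(scans=scans, subjects=subjects)


def _read_table(path, sep: str | None) -> pd.DataFrame:
    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                             keep_default_na=False, na_values=["", "NA"])
        else:
            df = pd.read_csv(path, sep=sep, dtype=str,
                             keep_default_na=False, na_values=["", "NA"])
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message carries line
        raise CohortParseError(f"{path}: {exc}") from exc
    return df


def write_cohort(cohort: Cohort, scans_path, subjects_path) -> None:
    """Write a cohort in the canonical dialect (comma, UTF-8, '.' decimals,
    rows ordered by subject_id then t)."""
    scans = cohort.scans.copy()
    scans.to_csv(scans_path, index=False, na_rep="NA")
    subj = cohort.subjects.copy()
    subj["csf_abeta_neg"] = subj["csf_abeta_neg"].map({True: "true", False: "false"})
    subj["csf_ptau_neg"] = subj["csf_ptau_neg"].map({True: "true", False: "false"})
    subj.to_csv(subjects_path, index=False, na_rep="NA")


def categorize_vr(cohort: Cohort) -> Mapping[str, VrCategory]:
    """Categorize each subject's visual-read sequence over time.

    Subjects need >= 2 scans with non-missing VR at all of them; others are
    skipped (logged as unclassifiable).  A negative baseline followed by any
    positive read is a converter even if a later read is negative again
    (first conversion wins).
    """
    out: dict[str, VrCategory] = {}
    unclassifiable: list[str] = []
    for sid, grp in cohort.scans.groupby("subject_id", sort=True):
        vr = grp.sort_values("t_years")["vr"]
        if len(vr) < 2 or vr.isna().any():
            unclassifiable.append(sid)
            continue
        seq = [v == "pos" for v in vr]
        baseline, follow = seq[0], seq[1:]
        if not baseline:
            out[sid] = VrCategory.converter_pos if any(follow) else VrCategory.stable_neg
        else:
            out[sid] = VrCategory.converter_neg if not all(follow) else VrCategory.stable_pos
    if unclassifiable:
        log.info("categorize_vr: %d unclassifiable subjects (missing VR or single scan)",
                 len(unclassifiable))
    return out
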