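"""End-to-end pipeline orchestration and report generation.

Stages: load -> ARC -> reference selection -> reliable-accumulation
thresholds (normative + GMM) -> accumulator classification -> baseline-CL
prediction thresholds -> trajectory models.  Outputs are a machine-readable
JSON summary plus delimited tables (demographics by tracer, accumulator
counts by VR category, PR curves, trajectory estimates).  Every output
embeds the seed and a hash of the configuration; re-running with the same
inputs and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .accumulation import (
    ReferenceCriteria,
    classify_accumulators,
    compute_arc,
    fit_gmm2,
    gmm_threshold,
    normative_threshold,
    select_reference,
)
from .cohort import Cohort, read_cohort
from .prediction import optimize_threshold
from .trajectories import LmeSpec, fit_with_bootstrap, stepwise_covariates

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    scans_path: str | None = None
    subjects_path: str | None = None
    seed: int = 0
    out_dir: str = "clarc_out"
    arc_rule: str = "last"
    criteria: ReferenceCriteria = field(default_factory=ReferenceCriteria)
    normative_level: float = 0.95
    gmm_level: float = 0.99
    n_boot_normative: int = 1000
    pr_n_opt: int = 500
    pr_n_ci: int = 1000
    pr_scenarios: tuple[str, ...] = ("f1",)
    lme_models: tuple[str, ...] = ("base",)
    lme_n_boot: int = 200
    simulate_if_missing: bool = True

    def validate(self) -> None:
        if self.scans_path is not None:
            for p in (self.scans_path, self.subjects_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        elif not self.simulate_if_missing:
            raise ValueError("no input files given and simulation disabled")

    def to_dict(self) -> dict:
        # out_dir is where results land, not part of what is computed; keeping
        # it out of the echoed config makes same-seed runs byte-identical
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SCENARIOS = {
    "f1": None,
    "precision0.7": ("precision", 0.7),
    "recall0.7": ("recall", 0.7),
    "specificity0.9": ("specificity", 0.9),
}


def _fmt_mean_sd(x: pd.Series) -> str:
    x = pd.to_numeric(x, errors="coerce").dropna()
    if len(x) == 0:
        return "NA"
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return f"{x.mean():.1f} ({sd:.1f})"


def _fmt_count(n: int, total: int) -> str:
    pct = 100.0 * n / total if total else 0.0
    return f"{n}/{total} ({pct:.0f}%)"


def summarize_demographics(cohort: Cohort, by: str = "tracer") -> pd.DataFrame:
    """Demographics table (mean (SD) or n/N (%)) overall and per tracer.

    Hypothesis-test columns are intentionally not computed.
    """
    from .cohort import categorize_vr

    subj = cohort.subjects.copy()
    baseline = cohort.scans[cohort.scans["t_years"] == 0].set_index("subject_id")
    subj["tracer"] = baseline.loc[subj["subject_id"], "tracer"].to_numpy()
    subj["cl0"] = baseline.loc[subj["subject_id"], "centiloid"].to_numpy()
    arc = compute_arc(cohort)
    subj = subj.set_index("subject_id")
    subj["arc"] = arc["arc"].reindex(subj.index)
    cats = categorize_vr(cohort)
    subj["vr_category"] = pd.Series({k: v.value for k, v in cats.items()}).reindex(subj.index)
    n_scans = cohort.scans.groupby("subject_id").size()
    subj["n_timepoints"] = n_scans.reindex(subj.index)

    groups = {"Overall": subj}
    if by == "tracer":
        for tr in sorted(subj["tracer"].unique()):
            groups[tr] = subj[subj["tracer"] == tr]

    rows = []

    def add(variable: str, level: str, fn) -> None:
        rows.append({"variable": variable, "level": level,
                     **{name: fn(g) for name, g in groups.items()}})

    add("Age, years", "", lambda g: _fmt_mean_sd(g["age0"]))
    for sex in ("M", "F"):
        add("Sex", sex, lambda g, s=sex: _fmt_count(int((g["sex"] == s).sum()), len(g)))
    for a in (0, 1, 2):
        add("APOE e4 alleles", str(a),
            lambda g, a=a: _fmt_count(int((g["apoe4"] == a).sum()),
                                      int(g["apoe4"].notna().sum())))
    add("APOE e4 alleles", "missing", lambda g: str(int(g["apoe4"].isna().sum())))
    for cat in ("stable_neg", "converter_pos", "converter_neg", "stable_pos"):
        add("VR category", cat,
            lambda g, c=cat: _fmt_count(int((g["vr_category"] == c).sum()), len(g)))
    for edu in ("compulsory", "upper_secondary", "post_secondary"):
        add("Education", edu,
            lambda g, e=edu: _fmt_count(int((g["education"] == e).sum()), len(g)))
    for cdr, label in ((0.0, "0"), (0.5, "0.5")):
        add("CDR", label,
            lambda g, c=cdr: _fmt_count(int((g["cdr"] == c).sum()),
                                        int(g["cdr"].notna().sum())))
    for k in (2, 3):
        add("N timepoints", str(k),
            lambda g, k=k: _fmt_count(int((g["n_timepoints"] == k).sum()), len(g)))
    add("Baseline CL", "", lambda g: _fmt_mean_sd(g["cl0"]))
    add("ARC, CL/year", "", lambda g: _fmt_mean_sd(g["arc"]))
    return pd.DataFrame(rows)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run all stages, write the report bundle to ``config.out_dir``.

    Returns the JSON-serializable summary dict.  A stage failure raises
    :class:`StageError` naming the stage; tables written by earlier stages
    are left on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }

    stage = "load"
    try:
        if cohort is None:
            if config.scans_path is not None:
                cohort = read_cohort(config.scans_path, config.subjects_path)
            else:
                from .simulate import SimConfig, generate
                sim = SimConfig(seed=derive_seed(config.seed, "simulate"))
                cohort, _ = generate(sim)
        summary["n_subjects"] = cohort.n_subjects
        summary["n_scans"] = cohort.n_scans

        stage = "demographics"
        demo = summarize_demographics(cohort)
        demo.to_csv(out / "demographics.csv", index=False)

        stage = "arc"
        arc = compute_arc(cohort, rule=config.arc_rule)

        stage = "reference_selection"
        groups = (pd.Series(dtype=object) if arc.empty
                  else select_reference(cohort, config.criteria, arc_table=arc))
        summary["n_reference"] = int((groups == "reference").sum())
        summary["n_exploratory"] = int((groups == "exploratory").sum())

        stage = "normative_threshold"
        ref_arcs = arc.loc[groups[groups == "reference"].index, "arc"].to_numpy()
        norm_est = normative_threshold(
            ref_arcs, level=config.normative_level,
            n_boot=config.n_boot_normative,
            seed=derive_seed(config.seed, "normative"))
        summary["normative_threshold"] = norm_est.to_dict()

        stage = "gmm_threshold"
        gmm = fit_gmm2(arc["arc"].to_numpy(), seed=derive_seed(config.seed, "gmm"))
        gmm_est = gmm_threshold(gmm, level=config.gmm_level, force=True)
        summary["gmm_threshold"] = gmm_est.to_dict()

        stage = "classification"
        acc = classify_accumulators(arc, norm_est, group_labels=groups)
        counts = (
            arc.loc[acc.index]
            .assign(status=acc)
            .groupby(["vr_category", "status"], dropna=False)
            .size()
            .rename("n")
            .reset_index()
        )
        counts.to_csv(out / "accumulators_by_vr.csv", index=False)
        summary["accumulators"] = {
            "n_accumulators": int((acc == "accumulator").sum()),
            "n_non_accumulators": int((acc == "non_accumulator").sum()),
            "by_vr_category": {
                f"{r.vr_category}|{r.status}": int(r.n) for r in counts.itertuples()
            },
        }

        stage = "prediction_threshold"
        expl = groups[groups == "exploratory"].index
        labels = (acc.loc[expl] == "accumulator")
        baseline = cohort.scans[cohort.scans["t_years"] == 0].set_index("subject_id")
        cl0 = baseline.loc[expl, "centiloid"].to_numpy()
        pr_summaries = {}
        curves = []
        for name in config.pr_scenarios:
            if name not in _SCENARIOS:
                raise ValueError(f"unknown PR scenario {name!r}")
            res = optimize_threshold(
                cl0, labels.to_numpy(), n_opt=config.pr_n_opt, n_ci=config.pr_n_ci,
                seed=derive_seed(config.seed, "pr", name),
                constraint=_SCENARIOS[name])
            pr_summaries[name] = res.optimal.to_dict()
            curves.append(res.curve.assign(scenario=name))
        pd.concat(curves, ignore_index=True).to_csv(out / "pr_curves.csv", index=False)
        summary["prediction_thresholds"] = pr_summaries

        stage = "trajectories"
        lme_summaries = {}
        frames = []
        for model in config.lme_models:
            if model == "base":
                spec = LmeSpec()
            elif model == "covariates":
                spec, _trail = stepwise_covariates(cohort, groups)
            elif model == "vr":
                spec = LmeSpec(fixed_terms=("time", "vr_category", "vr_category:time"),
                               random_structure="common_intercept_slope")
            else:
                raise ValueError(f"unknown LME model {model!r}")
            fit = fit_with_bootstrap(
                spec, cohort, groups, n_boot=config.lme_n_boot,
                seed=derive_seed(config.seed, "lme", model))
            lme_summaries[model] = fit.to_dict()
            frames.append(fit.estimates.reset_index().assign(model=model))
        pd.concat(frames, ignore_index=True).to_csv(out / "trajectory_estimates.csv", index=False)
        summary["trajectories"] = lme_summaries
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
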