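import numpy as np
import pandas as pd
import pytest

from clarc import Cohort, SimConfig, generate


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Two subjects, two scans each, hand-written values."""
    scans = pd.DataFrame({
        "subject_id": ["A", "A", "B", "B"],
        "t_years": [0.0, 2.0, 0.0, 3.0],
        "centiloid": [10.0, 16.0, -2.0, 1.0],
        "tracer": ["FMM", "FMM", "FBB", "FBB"],
        "vr": ["neg", "pos", "neg", "neg"],
    })
    subjects = pd.DataFrame({
        "subject_id": ["A", "B"],
        "age0": [70.0, 61.5],
        "sex": ["F", "M"],
        "apoe4": [1, 0],
        "education": ["compulsory", "post_secondary"],
        "cdr": [0.0, 0.5],
        "csf_abeta_neg": [False, True],
        "csf_ptau_neg": [pd.NA, True],
    })
    return Cohort(scans=scans, subjects=subjects)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=750), shared across tests."""
    return generate(SimConfig(seed=1234))


def make_cohort_from_trajectories(trajs, tracer="FMM", vr=None, subjects=None):
    """Build a cohort from {subject_id: [(t, cl), ...]} dictionaries."""
    rows = []
    for sid, pts in trajs.items():
        for i, (t, cl) in enumerate(pts):
            v = vr[sid][i] if vr else "neg"
            rows.append((sid, t, cl, tracer, v))
    scans = pd.DataFrame(rows, columns=["subject_id", "t_years", "centiloid", "tracer", "vr"])
    if subjects is None:
        subjects = pd.DataFrame({
            "subject_id": sorted(trajs),
            "age0": 65.0,
            "sex": "F",
            "apoe4": 0,
            "education": "compulsory",
            "cdr": 0.0,
            "csf_abeta_neg": True,
            "csf_ptau_neg": True,
        })
    return Cohort(scans=scans, subjects=subjects)
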