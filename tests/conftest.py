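import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memlong.datamodel import ROLE_MAIN, ROLE_VALIDATION, StudyDataset, SubjectSeries
from memlong.simulation import ScenarioConfig, generate_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_subject(sid, t, surrogate=None, true_exposure=None, outcome=None, W=None,
                 present=None, t_mem=None):
    return SubjectSeries(
        subject_id=sid,
        t_outcome=np.asarray(t, dtype=float),
        t_mem=t_mem,
        surrogate=surrogate,
        true_exposure=true_exposure,
        outcome=outcome,
        covariates=W,
        present=present,
    )


def relabel(series, new_id):
    s = copy.copy(series)
    s.subject_id = new_id
    return s


@pytest.fixture
def small_pair():
    """A small NI-NW EVS main/validation pair for fast end-to-end fits."""
    cfg = ScenarioConfig(scenario="NI-NW", n1=150, n2=80, li=5, seed=42)
    return generate_scenario(cfg)


@pytest.fixture
def small_ivs_pair():
    cfg = ScenarioConfig(scenario="NI-NW", design="ivs", n1=150, n2=60, li=5, seed=43)
    return generate_scenario(cfg)


def as_main(vs):
    """Re-role a validation dataset (with outcomes) as a main study whose
    surrogate IS the true exposure — the no-measurement-error limit."""
    subjects = []
    for s in vs.subjects:
        s2 = copy.copy(s)
        s2.surrogate = s.true_exposure.copy()
        subjects.append(s2)
    return StudyDataset(subjects, role=ROLE_MAIN)
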