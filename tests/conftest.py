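import numpy as np
import pytest

from bapt.canonical import bapt_v1
from bapt.instrument import (
    ADDITIVE_SUBSCORE,
    SINGLE_SELECT,
    CriterionSpec,
    Instrument,
    PatientRecord,
)
from bapt.weights import LevelWeights, normalise_respondent


@pytest.fixture(scope="session")
def canonical():
    return bapt_v1()


@pytest.fixture(scope="session")
def two_binary():
    """Two binary single-select criteria: 4 states, one trade-off task."""
    return Instrument(
        name="two_binary",
        criteria=(
            CriterionSpec("x", ("x0", "x1"), SINGLE_SELECT, {"x0": 0, "x1": 1}),
            CriterionSpec("y", ("y0", "y1"), SINGLE_SELECT, {"y0": 0, "y1": 1}),
        ),
    )


@pytest.fixture(scope="session")
def small():
    """Three criteria (3/2/3 levels): 18 states, closure-checkable by hand."""
    return Instrument(
        name="small",
        criteria=(
            CriterionSpec("a", ("a0", "a1", "a2"), SINGLE_SELECT,
                          {"a0": 0, "a1": 1, "a2": 2}),
            CriterionSpec("b", ("b0", "b1"), SINGLE_SELECT, {"b0": 0, "b1": 1}),
            CriterionSpec("c", ("c0", "c1", "c2"), SINGLE_SELECT,
                          {"c0": 0, "c1": 1, "c2": 2}),
        ),
    )


def make_truth(instrument, seed):
    """Random monotone level weights, worst 0, tops summing to 100."""
    rng = np.random.default_rng(seed)
    values = {}
    for c in instrument.criteria:
        gaps = rng.uniform(0.2, 1.0, c.n_levels - 1)
        values[c.name] = tuple(np.concatenate([[0.0], np.cumsum(gaps)]))
    w = LevelWeights("truth", values, order=instrument.criterion_names)
    return normalise_respondent(w)


@pytest.fixture
def truth_factory():
    return make_truth


def make_patient(**overrides):
    """Baseline eligible patient; override any field."""
    base = dict(
        patient_id="P1",
        age_years=50.0,
        sex="female",
        bmi=40.0,
        hba1c_pct=8.5,
        on_treatment=True,
        diabetes_duration_years=5.0,
        on_insulin=False,
        on_oral_meds=True,
        comorbidities=frozenset({"hypertension"}),
        pe_risk=False,
        asa_class=2,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def patient_factory():
    return make_patient
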