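import pytest

from coromrr import (
    PressureRecord,
    SimulationParams,
    correct_record,
    generate_cohort,
)


@pytest.fixture
def borderline_cp():
    """Corrected pressures for the textbook borderline-stenosis case:
    Pa 100 mmHg in both states, resting Pd/Pa 0.91, FFR 0.80, no height offset."""
    record = PressureRecord("LAD-borderline", 100.0, 91.0, 100.0, 80.0, 0.0)
    return correct_record(record)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free 23-vessel synthetic cohort with its ground truth."""
    params = SimulationParams(n_vessels=23, seed=20240603)
    return generate_cohort(params)
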