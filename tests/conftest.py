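import numpy as np
import pytest

from patchforage import (
    PolicyParams,
    ScheduleParams,
    generate_design,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_params() -> ScheduleParams:
    return ScheduleParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-subject, 16-session cohort for fast pipeline tests."""
    designs = generate_design(n_subjects=2, reps_per_combo=1, seed=7)
    return simulate_cohort(designs, PolicyParams(), seed=8)


@pytest.fixture(scope="session")
def study_cohort():
    """A full study-size cohort (4 subjects x 16 sessions)."""
    designs = generate_design(n_subjects=4, reps_per_combo=2, seed=42)
    return simulate_cohort(designs, PolicyParams(), seed=43)


def deterministic_recurrence(r0: float, tau: float, n: int) -> np.ndarray:
    """Independent oracle: the zero-noise delivery-time recurrence
    t_{k+1} = t_k + (1/r0) * exp(t_k / tau)."""
    t = 0.0
    out = []
    for _ in range(n):
        t = t + (1.0 / r0) * np.exp(t / tau)
        out.append(t)
    return np.array(out)
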