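import numpy as np
import pytest

from behentropy import (
    Ethogram,
    EventLog,
    GeneratorConfig,
    Interval,
    Session,
    default_ethogram,
)


@pytest.fixture(scope="session")
def ethogram():
    return default_ethogram()


@pytest.fixture
def abc_ethogram():
    return Ethogram(("A", "B", "C"))


def make_session(intervals, session_id="s1", phase="light", day=1,
                 window=(0, 3000)):
    return Session(
        session_id=session_id,
        phase=phase,
        day=day,
        window_start=window[0],
        window_end=window[1],
        intervals=[Interval(*iv) for iv in intervals],
    )


def make_log(intervals, dam_id="dam1", group="CTL", cohort="cohort1",
             **session_kwargs):
    return EventLog(
        dam_id=dam_id, group=group, cohort=cohort,
        sessions=[make_session(intervals, **session_kwargs)],
    )


@pytest.fixture
def toy_log():
    """The hand-checked 3-interval fixture: lick, nurse, lick."""
    return make_log(
        [(0, 10, "lick_groom"), (10, 40, "passive_nurse"),
         (40, 50, "lick_groom")],
        window=(0, 50),
    )


@pytest.fixture(scope="session")
def small_config(ethogram):
    """Scaled-down study: 2 cohorts x 1 dam/group, 2 days, short sessions."""
    return GeneratorConfig(
        ethogram=ethogram,
        n_days=2,
        sessions_per_day=2,
        session_length_s=600,
        n_cohorts=2,
        dams_per_group_per_cohort=1,
        n_dark_cohorts=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-design study, shared across tests (seed fixed)."""
    from behentropy import simulate_study

    return simulate_study(GeneratorConfig(seed=2024))


def random_irreducible_matrix(k, rng):
    """Random diagonal-zero row-stochastic matrix with all off-diag > 0."""
    P = rng.gamma(1.0, 1.0, size=(k, k)) + 0.05
    np.fill_diagonal(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)
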