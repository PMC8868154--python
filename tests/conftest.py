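import numpy as np
import pytest

from breathloop import synthetic
from breathloop.biofeedback import ScoreParams
from breathloop.synthetic import (
    AgentParams,
    CardiacParams,
    LearningParams,
    SyntheticCohortConfig,
    gen_session,
)


@pytest.fixture(scope="session")
def score_params():
    return ScoreParams()


@pytest.fixture(scope="session")
def full_session():
    """One complete synthetic subject-session with all streams and events."""
    cfg = SyntheticCohortConfig(seed=7)
    return gen_session("1", 2, 0.6, cfg, np.random.SeedSequence(99))


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-subject score-only cohort with short sessions (fast; used for
    bookkeeping/shape tests, not for statistical recovery)."""
    cfg = SyntheticCohortConfig(
        n_subjects=3,
        session_s=300.0,
        include_cardiac=False,
        include_events=False,
        seed=5,
    )
    records, truth = synthetic.gen_cohort(cfg)
    return records, truth


@pytest.fixture(scope="session")
def learning_cohort():
    """The default-condition 9-subject cohort (score streams only) with the
    biofeedback boost active — the end-to-end recovery surface."""
    cfg = SyntheticCohortConfig(
        n_subjects=9,
        include_cardiac=False,
        include_events=False,
        seed=20,
    )
    records, truth = synthetic.gen_cohort(cfg)
    return records, truth
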