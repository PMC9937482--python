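import numpy as np
import pytest

from vrgaze.synth import StudyConfig, simulate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete study shared across module tests."""
    cfg = StudyConfig(n_participants=2, n_scenes_encoding=6, n_old=3, n_new=3,
                      trial_duration_ms=4000)
    return simulate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def small_detection(small_study):
    from vrgaze.study import detect_study

    fix_table, measures = detect_study(small_study)
    return fix_table, measures
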