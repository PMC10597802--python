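import numpy as np
import pytest

from dfnckit import synth
from dfnckit.preprocess import Timecourse


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 4-group, 3-subjects-per-group synthetic dataset (C=8, T=120)."""
    truth = synth.default_ground_truth(n_components=8)
    cfg = synth.default_cohort_config()
    for g in cfg.groups.values():
        g.n = 3
    return synth.simulate_cohort_dataset(cfg, truth, n_timepoints=120, seed=7)


@pytest.fixture()
def conditioned_timecourse():
    """A simulated, fully conditioned single-subject time course."""
    from dfnckit import preprocess as pp

    truth = synth.default_ground_truth(n_components=6)
    seq = synth.simulate_state_sequence(
        synth.transition_matrix_for_occupancy(np.array([0.5, 0.3, 0.2]), 0.02),
        np.array([0.5, 0.3, 0.2]), 160, seed=3,
    )
    ts = synth.simulate_subject_timecourse(seq, truth.state_covariances, seed=4,
                                           subject_id="sub-1")
    out = pp.truncate_initial(ts, 10)
    out = pp.despike(out)
    out = pp.detrend(out)
    return pp.butterworth_lowpass(out)


@pytest.fixture()
def plain_timecourse():
    rng = np.random.default_rng(11)
    return Timecourse(values=rng.standard_normal((200, 5)), tr=2.0, subject_id="s0")
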