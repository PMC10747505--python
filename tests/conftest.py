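import numpy as np
import pytest

from handover import pipeline, synth


def make_row(size="small", weight_g=700, object_id=2, recording_number=5):
    return dict(
        size=size, weight_g=weight_g, object_id=object_id,
        recording_number=recording_number, dyad=0, giver="d00a", receiver="d00b",
    )


@pytest.fixture(scope="session")
def noiseless_trial():
    return synth.simulate_trial(make_row(), synth.NOISELESS, seed=3)


@pytest.fixture(scope="session")
def noisy_trial():
    return synth.simulate_trial(make_row("large", 1000, 4, 9), synth.DEFAULT_PARAMS, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """4 dyads, 480 analyzed trials, default generator conditions."""
    return pipeline.run_cohort(4, seed=5)


def closed_form_onset_frame(truth) -> int:
    """Independent closed-form target of the wrist-speed onset rule:
    first frame at which the minimum-jerk reach speed exceeds 5% of its
    peak (the reach stroke holds the trial's peak speed by design)."""
    t0 = truth.true_move_onset_frame
    T = truth.true_contact_frame - t0
    tau = synth.min_jerk_speed_crossing_tau(0.05)
    k = int(np.floor(tau * T)) + 1  # first integer frame strictly past the crossing
    return t0 + k
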