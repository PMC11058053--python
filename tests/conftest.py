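import numpy as np
import pytest

from hubnet import FluorescenceRecording, NormalisedTraces, SimulationConfig


@pytest.fixture
def small_recording() -> FluorescenceRecording:
    """3 cells x 8 frames, 1 s frames, stimulus at frame 4."""
    values = np.array(
        [
            [2.0, 2.0, 2.0, 2.0, 4.0, 6.0, 4.0, 2.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [1.0, 1.2, 1.1, 1.0, 3.0, 3.5, 2.0, 1.4],
        ]
    )
    return FluorescenceRecording(
        islet_id="testlet",
        values=values,
        frame_interval=1.0,
        labels=np.array(["pos", "neg", "neg"], dtype=object),
        stimulus_onset=4,
        coords=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
    )


@pytest.fixture
def flat_traces() -> NormalisedTraces:
    return NormalisedTraces(
        values=np.ones((2, 20)), frame_interval=1.0, stimulus_onset=5
    )


@pytest.fixture(scope="session")
def default_islet():
    """One simulated islet under the default study conditions, analysed
    once and shared across tests (the permutation test is the slow part)."""
    from hubnet import simulate_islet, analyse_recording

    cfg = SimulationConfig(seed=1)
    rec, truth = simulate_islet(cfg)
    result = analyse_recording(rec, seed=1)
    return cfg, rec, truth, result
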