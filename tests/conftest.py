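import numpy as np
import pytest

from walkweigh.preprocess import ValidSegment
from walkweigh.simulate import SimConfig, simulate_labelled_dataset


def make_segment(values, dt=0.1, eta=0.8):
    """Wrap raw values in a ValidSegment for estimator/feature tests."""
    values = np.asarray(values, dtype=float)
    return ValidSegment(values=values, start_index=0, end_index=len(values) - 1,
                        sampling_interval_s=dt, threshold_kg=float(eta * values.max()),
                        eta=eta)


@pytest.fixture(scope="session")
def labelled_traces():
    """30 simulated passages (10 per grade) with ground truth, fixed seed."""
    return simulate_labelled_dataset(10, SimConfig(), seed=42)
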