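import numpy as np
import pytest

from meanet.io import Recording, SpikeTrain


@pytest.fixture
def poisson_train():
    """Factory: homogeneous Poisson spike train on [0, duration)."""

    def make(rate=5.0, duration=60.0, seed=0, electrode_id=0):
        rng = np.random.default_rng(seed)
        n = rng.poisson(rate * duration)
        times = np.unique(rng.uniform(0.0, duration, n))
        return SpikeTrain(electrode_id, times, 0.0, duration)

    return make


@pytest.fixture
def small_recording():
    """Recording with spike counts 2 and 1 on two electrodes (duration 1 s)."""
    return Recording(
        device_id="dev",
        well_id="w0",
        condition="0uM",
        timepoint="baseline",
        duration=1.0,
        trains={
            0: SpikeTrain(0, np.array([0.10, 0.25]), 0.0, 1.0),
            1: SpikeTrain(1, np.array([0.30]), 0.0, 1.0),
        },
    )


def make_recording(counts, duration=10.0, seed=0, **meta):
    """Recording whose electrodes have exactly the given spike counts."""
    rng = np.random.default_rng(seed)
    trains = {}
    for eid, n in enumerate(counts):
        times = np.unique(rng.uniform(0.0, duration, n))
        while times.size < n:  # vanishingly rare duplicate draw
            times = np.unique(np.append(times, rng.uniform(0.0, duration)))
        trains[eid] = SpikeTrain(eid, np.sort(times), 0.0, duration)
    defaults = dict(
        device_id="dev", well_id="w0", condition="0uM", timepoint="baseline"
    )
    defaults.update(meta)
    return Recording(duration=duration, trains=trains, **defaults)
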