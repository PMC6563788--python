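import numpy as np
import pytest

from fespike import NeuronParams, SpikePattern, SpikeTrain, poisson_pattern


@pytest.fixture
def params():
    return NeuronParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pattern():
    """10 afferents, 100 ms, moderate rate: cheap but non-trivial."""
    return poisson_pattern(10, 40.0, 100.0, seed=7)


def random_train(rng, duration, n_max=6, dt=1.0):
    """Sorted, deduplicated grid-aligned spike times in [dt, duration]."""
    n = int(rng.integers(0, n_max + 1))
    k = np.unique(rng.integers(1, int(duration / dt) + 1, size=n))
    return SpikeTrain(k * dt)


def make_pattern(rng, n_afferents, duration, rate=40.0):
    trains = []
    p = rate / 1000.0
    for _ in range(n_afferents):
        hits = rng.random(int(duration)) < p
        trains.append(SpikeTrain((np.nonzero(hits)[0] + 1).astype(float)))
    return SpikePattern(tuple(trains), duration)
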