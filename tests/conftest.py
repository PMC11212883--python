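import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from m1beta.datamodel import AnalysisWindow, SpikeTrainSet
from m1beta.synth import OscillatoryRateSpec, gen_inhomogeneous_poisson


@pytest.fixture
def toy_set() -> SpikeTrainSet:
    """Three neurons, a dozen spikes, hand-placed for exact bin counting."""
    trains = {
        0: [0.0005, 0.0031, 0.0105, 0.0202],
        1: [0.0006, 0.0108, 0.0300, 0.0301],
        2: [0.0032, 0.0109, 0.0403, 0.0404],
    }
    return SpikeTrainSet.from_trains(trains, AnalysisWindow(0.0, 0.05))


@pytest.fixture
def labeled_set() -> SpikeTrainSet:
    """Small multi-population set with positions, for I/O round trips."""
    rng = np.random.default_rng(42)
    n = 100
    neurons = pd.DataFrame({
        "neuron_id": np.arange(n),
        "population": np.where(np.arange(n) < 60, "PT5B", "IT5A"),
        "layer": np.where(np.arange(n) < 60, "L5B", "L5A"),
        "x_um": rng.uniform(-150, 150, n),
        "y_um": rng.uniform(0, 1350, n),
        "z_um": rng.uniform(-150, 150, n),
    })
    counts = rng.poisson(20, n)
    ids = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, 2.0, counts.sum())
    return SpikeTrainSet(neurons, ids, times, AnalysisWindow(0.0, 2.0))


@pytest.fixture
def poisson_population() -> SpikeTrainSet:
    """Homogeneous 10 Hz Poisson population, 20 neurons, 4 s."""
    spec = OscillatoryRateSpec(baseline=10.0, duration=4.0)
    return gen_inhomogeneous_poisson(spec, 20, seed=7)
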