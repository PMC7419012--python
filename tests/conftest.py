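"""Shared fixtures: surrogate datasets, simulator runs, planted libraries.

Expensive simulator-backed fixtures are session-scoped so the condition
datasets and the coarse inference library are built once for the whole run.
"""

import numpy as np
import pytest

from olivenet.features import FeatureLibrary, FeatureSpec
from olivenet.model import NetworkConfig, NeuronParams, build_network, simulate
from olivenet.synthetic import SurrogateSpec, surrogate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_dataset():
    return surrogate_dataset(SurrogateSpec(
        kind="poisson", n_neurons=5, rate=1.5, duration=300.0, seed=7))


@pytest.fixture(scope="session")
def periodic_dataset():
    return surrogate_dataset(SurrogateSpec(
        kind="periodic", n_neurons=4, rate=1.0, period=1.0, duration=200.0,
        seed=8))


def _condition_run(g_i, g_c, seed, duration=150.0):
    net = build_network(NeuronParams(g_i=g_i),
                        NetworkConfig(mean_g_c=g_c, seed=seed))
    return simulate(net, duration, seed=seed, noise=True).dataset


@pytest.fixture(scope="session")
def con_datasets():
    """Control-condition simulations (printed means g_i=1.15, g_c=1.19)."""
    return [_condition_run(1.15, 1.19, seed) for seed in (1, 2, 3)]


@pytest.fixture(scope="session")
def pix_datasets():
    """Picrotoxin-condition simulations (printed means g_i=0.72, g_c=1.16)."""
    return [_condition_run(0.72, 1.16, seed) for seed in (1, 2, 3)]


@pytest.fixture(scope="session")
def cbx_datasets():
    """Carbenoxolone-condition simulations (printed means g_i=1.02, g_c=0.88)."""
    return [_condition_run(1.02, 0.88, seed) for seed in (1, 2)]


def make_planted_library(noise_rate=20.0, n_g=41, seed=0):
    """Synthetic feature library with a smooth invertible (g_i, g_c) map.

    Stands in for a simulator-backed library in inference machinery tests:
    each grid point's 67-vector is a smooth function of the conductances, so
    recovery accuracy reflects the inference alone.
    """
    rng = np.random.default_rng(seed)
    spec = FeatureSpec()
    axis = np.linspace(0.0, 2.0, n_g)
    mix = rng.normal(0, 1, (4, spec.length))
    coords, vecs = [], []
    for gi in axis:
        for gc in axis:
            basis = np.array([gi, gc, np.sin(1.3 * gi + 0.4),
                              np.cos(1.1 * gc - 0.2)])
            vecs.append(basis @ mix)
            coords.append((gi, gc, noise_rate))
    lib = FeatureLibrary(coords=np.array(coords), vectors=np.array(vecs),
                         spec=spec, g_i_axis=axis, g_c_axis=axis,
                         noise_rate=noise_rate)
    return lib.fit_pca()


@pytest.fixture(scope="session")
def planted_library():
    return make_planted_library()
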