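"""Shared fixtures: cached half-center simulations.

Simulations are expensive, so rasters are produced once per session through
a caching factory and shared between behavioural tests.
"""

import functools

import pytest

from hexcpg import NoiseSpec, build_scpg, cpg_parameters, run_network
from hexcpg.cpg_network import DEFAULT_NOISE_STD


@functools.lru_cache(maxsize=16)
def _scpg_raster(V_T: float, seed: int, duration: float):
    net = build_scpg(
        cpg_parameters(V_T), size=5, noise=NoiseSpec(std=DEFAULT_NOISE_STD)
    )
    return run_network(net, duration, seed=seed)


@pytest.fixture(scope="session")
def scpg_raster():
    """Factory returning a cached 5+5 half-center raster for (V_T, seed)."""

    def factory(V_T: float = -56.0, seed: int = 1, duration: float = 12000.0):
        return _scpg_raster(V_T, seed, duration)

    return factory
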