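"""Shared fixtures.

The full synthetic benchmark (sampling design, encoding, calibration, SLR
phase estimation with ablations and shot-drop variants, and the three
reconstruction modes) is expensive, so it is computed once per session and
shared by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from selfnav3d.pipeline import RunConfig, run_benchmark, simulate_slab
from selfnav3d.sampling import SamplingConfig, greedy_optimize


@pytest.fixture(scope="session")
def bench_report():
    """Full desk-scale benchmark with ablations and shot-drop variants."""
    return run_benchmark(RunConfig(run_ablations=True, run_shot_drop=True))


@pytest.fixture(scope="session")
def small_sim():
    """Light 4-coil simulated slab for unit tests of the operators."""
    return simulate_slab(RunConfig(ncoil=4))


@pytest.fixture(scope="session")
def design_180():
    config = SamplingConfig(ny=180, nkz=12, nshot=12, ry=3, dmax=15.0)
    return config, greedy_optimize(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
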