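"""Shared fixtures.

The expensive Monte Carlo study (all comparison protocols simulated and fit
over the ATT grid) is session-scoped so the acceptance tests that need it
share a single run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcaslopt.kinetics import KineticParams
from pcaslopt.pipeline import _protocol_seed, simulate_and_fit
from pcaslopt.reference import COMPARISON_SET, reference_protocols
from pcaslopt.simulator import NoiseModel

# study conditions of the Monte Carlo comparison: true CBF 50 mL/100 g/min,
# uniform ATT grid 0.5-2.0 s (0.02 s step), per-volume noise SD 1.3e-3 M0,
# 250 replicas per ATT sample
MC_SEED = 20201
MC_REPLICAS = 250
MC_ATT_STEP = 0.02
MC_CBF_TRUE = 50.0


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def protocols():
    return reference_protocols()


@pytest.fixture(scope="session")
def att_grid():
    n = int(round((2.0 - 0.5) / MC_ATT_STEP))
    return 0.5 + MC_ATT_STEP * np.arange(n + 1)


@pytest.fixture(scope="session")
def mc_study(protocols, att_grid):
    """Simulate and fit every comparison protocol (full data + halves)."""
    fits, halves = {}, {}
    for i, name in enumerate(COMPARISON_SET):
        _, f, h = simulate_and_fit(
            protocols[name], MC_CBF_TRUE, att_grid, NoiseModel(),
            MC_REPLICAS, _protocol_seed(MC_SEED, i),
        )
        fits[name], halves[name] = f, h
    return fits, halves
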