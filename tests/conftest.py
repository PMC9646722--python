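"""Shared fixtures.

The deep-settled baseline target is expensive (a few hundred simulated
cycles) and read-only, so it is built once per session and shared.
"""

import numpy as np
import pytest

from paceopt import (ModelParameters, ScalingFactors,
                     make_cell_specific_target)
from paceopt.trace import Trace


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_target(params):
    """Noise-free cell-specific target at sf = 1, settled to its rhythm."""
    return make_cell_specific_target(ScalingFactors(), params)


@pytest.fixture(scope="session")
def settled_state(baseline_target):
    from paceopt import CellState
    return CellState.from_dict(baseline_target.meta["final_state"])


def square_wave_trace(low=-80.0, high=40.0, high_ms=100.0, period_ms=400.0,
                      n_cycles=4, dt=0.1):
    """Synthetic periodic square wave with known metrics."""
    n_per = int(round(period_ms / dt))
    n_high = int(round(high_ms / dt))
    cyc = np.full(n_per, low)
    cyc[:n_high] = high
    vm = np.concatenate([np.full(n_per // 2, low)]
                        + [cyc] * n_cycles)
    return Trace(vm=vm, dt=dt)


@pytest.fixture
def square_trace():
    return square_wave_trace()
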