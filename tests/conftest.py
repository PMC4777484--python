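"""Shared fixtures.

The expensive simulations (classic 1500-ms train, the five pattern
exemplars) are session-scoped so that unit tests and the acceptance tests
share one run each.
"""

import numpy as np
import pytest

from frachh import (FractionalConfig, StepCurrentProtocol, simulate_classic,
                    simulate_hybrid)


@pytest.fixture(scope="session")
def classic_i18_trace():
    """Classic model, I = 18 for 1500 ms at dt = 0.001 (tonic spiking)."""
    return simulate_classic(
        protocol=StepCurrentProtocol(amplitude=18.0, duration=1500.0),
        dt=0.001)


@pytest.fixture(scope="session")
def quiescent_trace():
    """Classic model at I = 0 with default initial conditions, 100 ms."""
    return simulate_classic(
        protocol=StepCurrentProtocol(amplitude=0.0, duration=100.0),
        dt=0.001)


def _pattern_trace(gate, eta, I):
    return simulate_hybrid(
        fconfig=FractionalConfig(fractional_gate=gate, eta=eta, dt=0.01),
        protocol=StepCurrentProtocol(amplitude=I, duration=1500.0))


@pytest.fixture(scope="session")
def mmo_trace():
    """Mixed-mode oscillations: fractional n gate, eta=0.7, I=23."""
    return _pattern_trace("n", 0.7, 23.0)


@pytest.fixture(scope="session")
def ps_trace():
    """Phasic spiking: fractional n gate, eta=0.4, I=8."""
    return _pattern_trace("n", 0.4, 8.0)


@pytest.fixture(scope="session")
def swb_trace():
    """Square-wave bursting: fractional h gate, eta=0.4, I=10."""
    return _pattern_trace("h", 0.4, 10.0)


@pytest.fixture(scope="session")
def ppb_pituitary_trace():
    """Pituitary-type pseudo-plateau bursting: h gate, eta=0.2, I=20."""
    return _pattern_trace("h", 0.2, 20.0)


@pytest.fixture(scope="session")
def ppb_cardiac_trace():
    """Cardiac-type pseudo-plateau bursting: h gate, eta=0.2, I=9."""
    return _pattern_trace("h", 0.2, 9.0)


def naive_l1_gate_sequence(x0, alpha, beta, eta, dt, n_steps):
    """Reference implementation of the L1 update, written directly from
    the discretized equations with an O(N) inner loop per step and the
    weights recomputed from scratch each step.  Deliberately independent
    of the package's vectorized kernels.
    """
    import math
    xs = [float(x0)]
    mems = [0.0]
    c0 = dt ** eta * math.gamma(2.0 - eta)
    for N in range(1, n_steps + 1):
        mem = 0.0
        for k in range(0, N - 1):
            w = (N - k) ** (1.0 - eta) - (N - 1 - k) ** (1.0 - eta)
            mem -= (xs[k + 1] - xs[k]) * w
        x_prev = xs[-1]
        x_new = c0 * (alpha * (1.0 - x_prev) - beta * x_prev) + x_prev + mem
        xs.append(x_new)
        mems.append(mem)
    return np.array(xs), np.array(mems)
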