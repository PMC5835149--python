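"""Shared fixtures.

The expensive simulation artifacts (the double-well pipeline field, the
long equilibrium trajectories) are session-scoped and shared between the
module tests and the acceptance suite, so each is computed once per run.
All seeds are fixed: every fixture is deterministic.
"""

import numpy as np
import pytest

import tmrc

# Study conditions for the worked examples: inverse temperature beta = 2
# (temperature 1/2).  At this temperature the curved double well has one
# slow timescale ~6 well separated from the fast ones (~0.8), and the
# seven-well circular potential keeps six slow timescales above ~1.7.
BETA = 2.0


@pytest.fixture(scope="session")
def double_well():
    return tmrc.make_potential("double_well")


@pytest.fixture(scope="session")
def seven_well():
    return tmrc.make_potential("circular_well", k=7)


@pytest.fixture(scope="session")
def harmonic_1d():
    return tmrc.make_potential("harmonic", dimension=1)


@pytest.fixture(scope="session")
def dw_grid_config():
    """The double-well pipeline config: 40x30 grid on [-2,2]x[-1,2],
    lag 2, the fixed example observables, M = 1000."""
    return tmrc.PipelineConfig(
        potential="double_well",
        beta=BETA,
        lag=2.0,
        dt=1e-3,
        M=1000,
        r=1,
        r_out=1,
        eval_points={
            "mode": "grid", "lower": [-2, -1], "upper": [2, 2], "counts": [40, 30],
        },
        observables={
            "mode": "explicit",
            "coefficients": tmrc.DOUBLE_WELL_COEFFICIENTS.tolist(),
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def dw_field(dw_grid_config):
    """Full pipeline output on the double-well grid (the slow fixture)."""
    return tmrc.compute_rc(dw_grid_config)


@pytest.fixture(scope="session")
def dw_traj(double_well):
    """10^6-step equilibrium trajectory of the double well, stride 1e-2."""
    spec = tmrc.IntegratorSpec(dt=1e-2, beta=BETA, seed=123)
    return tmrc.simulate_trajectory(
        double_well, spec, [1.0, 0.0], total_time=10_000.0, stride=1e-2
    )


@pytest.fixture(scope="session")
def sw_traj(seven_well):
    """10^6-step equilibrium trajectory of the seven-well, stride 1e-2."""
    spec = tmrc.IntegratorSpec(dt=1e-2, beta=BETA, seed=42)
    return tmrc.simulate_trajectory(
        seven_well, spec, [1.0, 0.0], total_time=10_000.0, stride=1e-2
    )


@pytest.fixture(scope="session")
def sw_ulam_spectrum(sw_traj):
    """Symmetrized 40x40 Ulam spectrum of the seven-well at lag 0.1."""
    part = tmrc.BoxPartition([-2, -2], [2, 2], [40, 40])
    op = tmrc.ulam_full(sw_traj, part, lag=0.1, symmetrize=True)
    return tmrc.spectrum(op, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def circle_cloud(n=200, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    pts = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return pts + rng.normal(0, noise, pts.shape), theta
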