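"""Euler-Maruyama integration of the overdamped Langevin equation.

Two sampling modes are provided:

* :func:`simulate_trajectory` -- one long trajectory recorded at a fixed
  stride, used for Ulam discretizations and equilibrium statistics;
* :func:`burst_endpoints` -- from each of ``ell`` start points, ``M``
  independent short trajectories of length ``lag``; only the endpoints are
  kept.  These bursts are the empirical stand-in for the transition density
  p^t(x, .) and feed the observable embedding.

Reproducibility contract: one root seed; each start point draws its noise
from a dedicated substream keyed by the root seed and a hash of its own
coordinates, and realization ``m`` always consumes column ``m`` of each
step's ``(M, n)`` Gaussian block.  Endpoint arrays are therefore
bit-identical no matter how the start points are chunked, ordered or
distributed over workers, and permuting the start points permutes the
endpoint rows exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .errors import IntegrationBlowupError, ValidationError
from .potentials import Potential

__all__ = [
    "IntegratorSpec",
    "Trajectory",
    "BurstEnsemble",
    "simulate_trajectory",
    "burst_endpoints",
]

#: any coordinate beyond this magnitude aborts the integration
BLOWUP_LIMIT = 1e6


@dataclass(frozen=True)
class IntegratorSpec:
    """Euler-Maruyama parameters.

    ``beta`` is the inverse temperature of the thermostat; the per-step
    noise amplitude is ``sqrt(2 * dt / beta)`` per coordinate.
    ``beta = inf`` disables the noise (pure gradient descent).
    """

    dt: float
    beta: float
    seed: int = 0
    scheme: str = "euler-maruyama"

    def __post_init__(self):
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if not self.beta > 0:
            raise ValidationError(f"beta must be positive, got {self.beta}")
        if self.scheme != "euler-maruyama":
            raise ValidationError(f"unknown scheme {self.scheme!r}")

    @property
    def noise_amplitude(self) -> float:
        return float(np.sqrt(2.0 * self.dt / self.beta))

    def with_seed(self, seed: int) -> "IntegratorSpec":
        return replace(self, seed=int(seed))


@dataclass
class Trajectory:
    """States of one long run, recorded every ``stride`` time units."""

    states: np.ndarray  # (N, n), row 0 is the initial condition
    stride: float
    integrator: IntegratorSpec

    def __len__(self):
        return len(self.states)

    @property
    def dimension(self) -> int:
        return self.states.shape[1]

    def subsample(self, count: int, seed: int) -> np.ndarray:
        """Uniform without-replacement subsample of the recorded states."""
        if count > len(self.states):
            raise ValidationError("subsample larger than trajectory")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(997,)))
        idx = rng.choice(len(self.states), size=count, replace=False)
        return self.states[np.sort(idx)]


@dataclass
class BurstEnsemble:
    """Lag-t endpoints of M independent realizations per start point."""

    start_points: np.ndarray  # (ell, n)
    endpoints: np.ndarray  # (ell, M, n)
    lag: float
    integrator: IntegratorSpec

    @property
    def M(self) -> int:
        return self.endpoints.shape[1]

    @property
    def dimension(self) -> int:
        return self.start_points.shape[1]


def _point_stream(seed: int, x0: np.ndarray) -> np.random.Generator:
    """Noise substream keyed by the root seed and the start point itself."""
    digest = hashlib.blake2b(np.ascontiguousarray(x0).tobytes(), digest_size=16)
    words = tuple(int(w) for w in np.frombuffer(digest.digest(), dtype=np.uint32))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=words))


def _steps(interval: float, dt: float, what: str) -> int:
    """Number of dt-steps in ``interval``; must be an integer multiple."""
    n = interval / dt
    if abs(n - round(n)) > 1e-8 * max(1.0, n):
        raise ValidationError(f"{what}={interval} is not an integer multiple of dt={dt}")
    return int(round(n))


def _check_finite(x, step):
    if not np.all(np.isfinite(x)) or np.any(np.abs(x) > BLOWUP_LIMIT):
        raise IntegrationBlowupError(step)


def simulate_trajectory(
    potential: Potential,
    spec: IntegratorSpec,
    x0,
    total_time: float,
    stride: float,
) -> Trajectory:
    """Integrate one path for ``total_time``, recording every ``stride``.

    Returns ``floor(total_time / stride) + 1`` states including ``x0``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (potential.dimension,):
        raise ValidationError(f"x0 must have shape ({potential.dimension},)")
    sub = _steps(stride, spec.dt, "stride")
    if sub < 1:
        raise ValidationError("stride must be at least dt")
    n_records = int(np.floor(total_time / stride + 1e-12))
    states = np.empty((n_records + 1, x0.size))
    states[0] = x0
    if n_records == 0:
        return Trajectory(states, stride, spec)

    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(1_000_003, 0))
    )
    sig = spec.noise_amplitude
    dt = spec.dt
    x = x0.copy()
    grad = potential.gradient
    # noise drawn in record-sized blocks: cheap, and stream order is fixed
    for rec in range(1, n_records + 1):
        if sig > 0.0:
            noise = rng.standard_normal((sub, x.size)) * sig
            for s in range(sub):
                x += -grad(x) * dt + noise[s]
        else:
            for _ in range(sub):
                x += -grad(x) * dt
        _check_finite(x, rec * sub)
        states[rec] = x
    return Trajectory(states, stride, spec)


def burst_endpoints(
    potential: Potential,
    spec: IntegratorSpec,
    start_points,
    lag: float,
    M: int,
) -> BurstEnsemble:
    """M lag-t endpoints from each start point (independent substreams)."""
    starts = np.atleast_2d(np.asarray(start_points, dtype=float))
    if starts.shape[1] != potential.dimension:
        raise ValidationError(
            f"start points have dimension {starts.shape[1]}, "
            f"potential has {potential.dimension}"
        )
    if M < 1:
        raise ValidationError("M must be at least 1")
    nsteps = _steps(lag, spec.dt, "lag")
    n = starts.shape[1]
    out = np.empty((len(starts), M, n))
    sig = spec.noise_amplitude
    dt = spec.dt
    grad = potential.gradient
    # noise for one start point is at most ~32 MB before we fall back to
    # stepwise draws; both paths consume the identical stream sequence.
    prealloc = nsteps * M * n <= 4_000_000
    for i, x0 in enumerate(starts):
        rng = _point_stream(spec.seed, x0)
        x = np.tile(x0, (M, 1))
        if nsteps == 0:
            out[i] = x
            continue
        if sig > 0.0 and prealloc:
            noise = rng.standard_normal((nsteps, M, n)) * sig
            for s in range(nsteps):
                x += -grad(x) * dt + noise[s]
        elif sig > 0.0:
            for s in range(nsteps):
                x += -grad(x) * dt + rng.standard_normal((M, n)) * sig
        else:
            for _ in range(nsteps):
                x += -grad(x) * dt
        _check_finite(x, nsteps)
        out[i] = x
    return BurstEnsemble(starts, out, float(lag), spec)
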