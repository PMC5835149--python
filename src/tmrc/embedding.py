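"""Observable embedding of transition densities.

The transition density p^t(x, .) attached to a state x is embedded into
R^(2r+1) by pairing it with 2r+1 generic observables eta_j,

    z_j(x) = <p^t(x, .), eta_j> = E[eta_j(X_t) | X_0 = x],

which is a Koopman expectation and is estimated by the Monte-Carlo mean of
eta_j over the M burst endpoints launched from x.  If the transition
densities concentrate near an r-dimensional manifold in density space, the
point cloud {z(x_i)} concentrates near its diffeomorphic image in R^(2r+1)
(a generic linear map embeds an r-manifold into 2r+1 dimensions), which the
diffusion map then parametrizes.

Observables are linear by default, eta_j(x) = a_j . x with coefficients
drawn uniformly from [-1, 1].  Linear observables are not bounded, but the
exponential decay of p^t in the confining potentials used here makes the
pairing finite; bounded custom observables are accepted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .potentials import Potential
from .sampler import BurstEnsemble, IntegratorSpec, burst_endpoints

__all__ = [
    "ObservableSet",
    "EmbeddedCloud",
    "draw_linear_observables",
    "double_well_observables",
    "mc_koopman",
    "embed_points",
    "DOUBLE_WELL_COEFFICIENTS",
]

#: the fixed three-observable coefficient set used in the curved double-well
#: worked example (r = 1, so 2r+1 = 3 linear observables on R^2)
DOUBLE_WELL_COEFFICIENTS = np.array(
    [
        [-0.2630, -0.3186],
        [-0.2246, 0.0969],
        [0.1564, 0.0783],
    ]
)


@dataclass(frozen=True)
class ObservableSet:
    """2r+1 observables R^n -> R, linear (coefficient matrix) or custom."""

    n: int
    r: int
    kind: str = "linear"  # "linear" | "custom"
    coefficients: np.ndarray | None = None  # (2r+1, n) when linear
    functions: Sequence[Callable] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind == "linear":
            c = np.asarray(self.coefficients, dtype=float)
            if c.shape != (self.count, self.n):
                raise ValidationError(
                    f"coefficients must have shape {(self.count, self.n)}, got {c.shape}"
                )
            object.__setattr__(self, "coefficients", c)
        elif self.kind == "custom":
            if self.functions is None or len(self.functions) != self.count:
                raise ValidationError(f"custom kind needs {self.count} functions")
        else:
            raise ValidationError(f"unknown observable kind {self.kind!r}")

    @property
    def count(self) -> int:
        return 2 * self.r + 1

    def __call__(self, x) -> np.ndarray:
        """Evaluate all observables; shape (..., n) -> (..., 2r+1)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return x @ self.coefficients.T
        return np.stack([np.asarray(f(x), dtype=float) for f in self.functions], axis=-1)


@dataclass
class EmbeddedCloud:
    """Embedded points z_i with Monte-Carlo standard errors and provenance."""

    points: np.ndarray  # (ell, 2r+1)
    start_points: np.ndarray  # (ell, n)
    mc_stderr: np.ndarray  # (ell, 2r+1)
    observables: ObservableSet
    lag: float
    M: int

    def __len__(self):
        return len(self.points)


def _full_row_rank(c: np.ndarray) -> bool:
    if len(c) <= c.shape[1]:
        return np.linalg.matrix_rank(c) == len(c)
    # more functionals than dimensions: require pairwise non-collinearity
    norms = np.linalg.norm(c, axis=1)
    if np.any(norms == 0):
        return False
    u = c / norms[:, None]
    g = np.abs(u @ u.T)
    np.fill_diagonal(g, 0.0)
    return np.all(g < 1.0 - 1e-12)


def draw_linear_observables(
    n: int, r: int, seed: int, low: float = -1.0, high: float = 1.0
) -> ObservableSet:
    """Draw 2r+1 linear observables with i.i.d. uniform coefficients.

    Degenerate draws (coefficient matrix without full row rank, or with
    collinear rows when 2r+1 > n) are rejected and redrawn from the next
    substream.
    """
    if not low < high:
        raise ValidationError("need low < high")
    for attempt in range(128):
        ss = np.random.SeedSequence(seed, spawn_key=(attempt,))
        c = np.random.default_rng(ss).uniform(low, high, size=(2 * r + 1, n))
        if _full_row_rank(c):
            return ObservableSet(n=n, r=r, kind="linear", coefficients=c, seed=seed)
    raise ValidationError("could not draw a non-degenerate observable set")


def double_well_observables() -> ObservableSet:
    """The fixed coefficient set of the double-well worked example."""
    return ObservableSet(n=2, r=1, kind="linear", coefficients=DOUBLE_WELL_COEFFICIENTS)


def mc_koopman(ensemble: BurstEnsemble, obs: ObservableSet) -> EmbeddedCloud:
    """Monte-Carlo Koopman expectations of the observables at each start.

    ``points[i, j]`` is the mean of ``eta_j`` over the M endpoints of start
    point i; ``mc_stderr[i, j]`` the sample standard deviation over
    realizations divided by sqrt(M).
    """
    if ensemble.dimension != obs.n:
        raise ValidationError(
            f"ensemble dimension {ensemble.dimension} != observable dimension {obs.n}"
        )
    if ensemble.M == 0:
        raise ValidationError("ensemble has no realizations")
    vals = obs(ensemble.endpoints)  # (ell, M, 2r+1)
    points = vals.mean(axis=1)
    if ensemble.M > 1:
        stderr = vals.std(axis=1, ddof=1) / np.sqrt(ensemble.M)
    else:
        stderr = np.zeros_like(points)
    return EmbeddedCloud(
        points=points,
        start_points=ensemble.start_points,
        mc_stderr=stderr,
        observables=obs,
        lag=ensemble.lag,
        M=ensemble.M,
    )


def embed_points(
    potential: Potential,
    spec: IntegratorSpec,
    obs: ObservableSet,
    start_points,
    lag: float,
    M: int,
) -> EmbeddedCloud:
    """Bursts followed by Monte-Carlo Koopman evaluation (one call).

    Bit-identical to running :func:`tmrc.sampler.burst_endpoints` and
    :func:`mc_koopman` separately with the same seed.
    """
    ensemble = burst_endpoints(potential, spec, start_points, lag, M)
    return mc_koopman(ensemble, obs)
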