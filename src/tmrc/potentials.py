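"""Analytic potential-energy landscapes and their Boltzmann densities.

The dynamics studied throughout the package is the overdamped Langevin
diffusion

    dX_t = -grad V(X_t) dt + sqrt(2/beta) dW_t,

whose unique equilibrium density is the Boltzmann density
rho(x) = exp(-beta V(x)) / Z.  This module provides the example landscapes
used in the worked examples (a curved double well, a circular k-well in two
and ten dimensions, and two quadruple wells with qualitatively different
transition regions), plus harmonic and user-defined potentials.

All energies and gradients are vectorized over a trailing coordinate axis:
arrays of shape ``(..., n)`` yield energies of shape ``(...,)`` and
gradients of shape ``(..., n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Potential",
    "BoltzmannDensity",
    "make_potential",
    "boltzmann_density",
    "BUILTIN_POTENTIALS",
]


@dataclass(frozen=True)
class Potential:
    """An analytic energy landscape on R^n with an explicit gradient."""

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    label: str = "custom"
    params: dict = field(default_factory=dict)

    def __call__(self, x) -> np.ndarray:
        return self.energy(np.asarray(x, dtype=float))

    def grad(self, x) -> np.ndarray:
        return self.gradient(np.asarray(x, dtype=float))


def _check_xy(x, dim):
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != dim:
        raise ValidationError(f"expected last axis of length {dim}, got shape {x.shape}")
    return x


# -- curved double well: two wells at (+-1, 0) joined by the parabola x2 = 1 - x1^2


def _dw_energy(x):
    x = _check_xy(x, 2)
    x1, x2 = x[..., 0], x[..., 1]
    return (x1**2 - 1) ** 2 + 2 * (x1**2 + x2 - 1) ** 2


def _dw_gradient(x):
    x = _check_xy(x, 2)
    x1, x2 = x[..., 0], x[..., 1]
    c = x1**2 + x2 - 1
    return np.stack([4 * x1 * (x1**2 - 1) + 8 * x1 * c, 4 * c], axis=-1)


# -- circular k-well: cos(k theta) on an annulus stiffly confined to radius 1


def _circ_energy_2d(x, k):
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    r = np.sqrt(x1**2 + x2**2)
    # two-argument, quadrant-aware angle: atan2(x2, x1)
    return np.cos(k * np.arctan2(x2, x1)) + 10 * (r - 1) ** 2


def _circ_gradient_2d(x, k):
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    r2 = np.maximum(x1**2 + x2**2, 1e-24)  # gradient undefined at the origin
    r = np.sqrt(r2)
    s = -k * np.sin(k * np.arctan2(x2, x1))
    g1 = s * (-x2 / r2) + 20 * (r - 1) * (x1 / r)
    g2 = s * (x1 / r2) + 20 * (r - 1) * (x2 / r)
    return np.stack([g1, g2], axis=-1)


def _circ10_energy(x, k):
    x = _check_xy(x, 10)
    return _circ_energy_2d(x[..., :2], k) + 10 * np.sum(x[..., 2:] ** 2, axis=-1)


def _circ10_gradient(x, k):
    x = _check_xy(x, 10)
    g = np.empty_like(x)
    g[..., :2] = _circ_gradient_2d(x[..., :2], k)
    g[..., 2:] = 20 * x[..., 2:]
    return g


# -- quadruple wells at (+-1, +-1); "hilly" blocks the diagonal with a central
#    bump, "flat" leaves a featureless plateau between narrow wells.


def _hilly_energy(x):
    x = _check_xy(x, 2)
    x1, x2 = x[..., 0], x[..., 1]
    return (x1**2 - 1) ** 2 + (x2**2 - 1) ** 2 + 5 * np.exp(-5 * (x1**2 + x2**2))


def _hilly_gradient(x):
    x = _check_xy(x, 2)
    x1, x2 = x[..., 0], x[..., 1]
    e = np.exp(-5 * (x1**2 + x2**2))
    return np.stack(
        [4 * x1 * (x1**2 - 1) - 50 * x1 * e, 4 * x2 * (x2**2 - 1) - 50 * x2 * e],
        axis=-1,
    )


_FLAT_CENTERS = ((1, 1), (1, -1), (-1, -1), (-1, 1))


def _flat_energy(x):
    x = _check_xy(x, 2)
    x1, x2 = x[..., 0], x[..., 1]
    v = np.ones(np.broadcast(x1, x2).shape)
    for c1, c2 in _FLAT_CENTERS:
        s = (x1 - c1) ** 2 + (x2 - c2) ** 2
        v = v - np.exp(-10 * s**2)
    return v


def _flat_gradient(x):
    x = _check_xy(x, 2)
    x1, x2 = x[..., 0], x[..., 1]
    g = np.zeros_like(x)
    for c1, c2 in _FLAT_CENTERS:
        s = (x1 - c1) ** 2 + (x2 - c2) ** 2
        w = 40 * s * np.exp(-10 * s**2)
        g[..., 0] += w * (x1 - c1)
        g[..., 1] += w * (x2 - c2)
    return g


def _harmonic_energy(x):
    x = np.asarray(x, dtype=float)
    return 0.5 * np.sum(x**2, axis=-1)


def _harmonic_gradient(x):
    return np.array(x, dtype=float, copy=True)


def _fd_gradient(energy, step=1e-6):
    """Central-difference fallback gradient for user potentials (slower)."""

    def grad(x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        for j in range(x.shape[-1]):
            e = np.zeros(x.shape[-1])
            e[j] = step
            g[..., j] = (energy(x + e) - energy(x - e)) / (2 * step)
        return g

    return grad


def _positive_int_k(params):
    k = params.get("k", 7)
    if not (isinstance(k, (int, np.integer)) and k > 0):
        raise ValidationError(f"k must be a positive integer, got {k!r}")
    return int(k)


BUILTIN_POTENTIALS = (
    "double_well",
    "circular_well",
    "circular_well_10d",
    "quad_hilly",
    "quad_flat",
    "harmonic",
    "custom",
)


def make_potential(name: str, params: dict | None = None, **kwargs) -> Potential:
    """Build a potential by name.

    Parameters
    ----------
    name
        One of ``double_well``, ``circular_well`` (parameter ``k``),
        ``circular_well_10d`` (``k``), ``quad_hilly``, ``quad_flat``,
        ``harmonic`` (``dimension``), or ``custom`` (``energy`` callable,
        ``dimension``, optional ``gradient``).
    params
        Parameter mapping; keyword arguments are merged on top.
    """
    p = dict(params or {})
    p.update(kwargs)
    if name == "double_well":
        return Potential(2, _dw_energy, _dw_gradient, "double_well")
    if name == "circular_well":
        k = _positive_int_k(p)
        return Potential(
            2,
            lambda x, k=k: _circ_energy_2d(_check_xy(x, 2), k),
            lambda x, k=k: _circ_gradient_2d(_check_xy(x, 2), k),
            f"circular_well_k{k}",
            {"k": k},
        )
    if name == "circular_well_10d":
        k = _positive_int_k(p)
        return Potential(
            10,
            lambda x, k=k: _circ10_energy(x, k),
            lambda x, k=k: _circ10_gradient(x, k),
            f"circular_well_10d_k{k}",
            {"k": k},
        )
    if name == "quad_hilly":
        return Potential(2, _hilly_energy, _hilly_gradient, "quad_hilly")
    if name == "quad_flat":
        return Potential(2, _flat_energy, _flat_gradient, "quad_flat")
    if name == "harmonic":
        dim = int(p.get("dimension", 1))
        return Potential(dim, _harmonic_energy, _harmonic_gradient, f"harmonic_{dim}d")
    if name == "custom":
        if "energy" not in p or "dimension" not in p:
            raise ConfigurationError("custom potential needs 'energy' and 'dimension'")
        energy = p["energy"]
        grad = p.get("gradient") or _fd_gradient(energy)
        return Potential(int(p["dimension"]), energy, grad, p.get("label", "custom"))
    raise ConfigurationError(
        f"unknown potential {name!r}; choose from {BUILTIN_POTENTIALS}"
    )


@dataclass(frozen=True)
class BoltzmannDensity:
    """The (by default unnormalized) equilibrium density exp(-beta V)."""

    potential: Potential
    beta: float
    normalizer: float | None = None  # None means unnormalized

    def log_density(self, x) -> np.ndarray:
        lz = 0.0 if self.normalizer is None else np.log(self.normalizer)
        return -self.beta * self.potential(x) - lz

    def __call__(self, x) -> np.ndarray:
        return np.exp(self.log_density(x))

    def ratio(self, x, y) -> np.ndarray:
        """rho(x)/rho(y) = exp(-beta (V(x) - V(y))), exact in log space."""
        return np.exp(-self.beta * (self.potential(x) - self.potential(y)))

    def normalized(self, box, npts: int = 257) -> "BoltzmannDensity":
        """Return a copy with Z computed by trapezoid quadrature on ``box``.

        ``box`` is a sequence of (low, high) pairs, one per dimension; the
        tensor grid uses ``npts`` nodes per axis (dimension <= 3).
        """
        box = [(float(a), float(b)) for a, b in box]
        dim = self.potential.dimension
        if len(box) != dim:
            raise ValidationError(f"box must have {dim} (low, high) pairs")
        if dim > 3:
            raise ValidationError("quadrature normalization supported for n <= 3")
        axes = [np.linspace(a, b, npts) for a, b in box]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack(grids, axis=-1)
        vals = np.exp(-self.beta * self.potential(pts))
        for ax in axes[::-1]:
            vals = np.trapezoid(vals, ax, axis=-1)
        return BoltzmannDensity(self.potential, self.beta, float(vals))


def boltzmann_density(potential: Potential, beta: float) -> BoltzmannDensity:
    """Unnormalized Boltzmann density exp(-beta V) for ``potential``."""
    if not beta > 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    return BoltzmannDensity(potential, float(beta))
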