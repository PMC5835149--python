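"""End-to-end reaction-coordinate pipeline.

The five stages: (1) choose evaluation points (a grid, a trajectory
subsample, or explicit points), (2) choose 2r+1 observables, (3) burst-
sample M lag-t endpoints per point and average the observables (the
embedded cloud), (4) fit a diffusion map to the cloud, (5) read off
xi_bar(x_i) = Psi(z_i).  The embedded cloud itself (step 3) doubles as the
(2r+1)-dimensional fallback coordinate that skips the manifold-learning
step.  All randomized stages draw named substreams of one root seed, so a
config determines its output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .embedding import (
    EmbeddedCloud,
    ObservableSet,
    draw_linear_observables,
    embed_points,
    mc_koopman,
)
from .errors import ConfigurationError, ValidationError
from .manifold_learning import DiffusionMapModel, evaluate_psi, fit_diffusion_map
from .potentials import Potential, make_potential
from .sampler import IntegratorSpec, Trajectory, burst_endpoints, simulate_trajectory
from .spectral import SpectrumResult, spectrum, ulam_projected

__all__ = [
    "PipelineConfig",
    "ReactionCoordinateField",
    "generate_eval_points",
    "compute_rc",
    "extend_rc",
    "compare_coordinates",
]

# named substreams of the root seed
_STREAM_OBSERVABLES = 11
_STREAM_BURSTS = 13
_STREAM_TRAJECTORY = 17
_STREAM_SUBSAMPLE = 19
_STREAM_NYSTROM = 23

#: refuse tensor grids beyond this size
MAX_GRID_POINTS = 10_000_000


def derive_seed(root_seed: int, stream: int) -> int:
    """A deterministic 31-bit child seed for a named substream."""
    state = np.random.SeedSequence(root_seed, spawn_key=(stream,)).generate_state(1)
    return int(state[0]) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    ``eval_points`` is one of
    ``{"mode": "grid", "lower": [...], "upper": [...], "counts": [...]}``,
    ``{"mode": "subsample", "x0": [...], "total_time": ..., "stride": ...,
    "count": ...}`` or ``{"mode": "explicit", "points": [[...], ...]}``.
    ``observables`` is ``{"mode": "random", "low": -1.0, "high": 1.0}`` or
    ``{"mode": "explicit", "coefficients": [[...], ...]}``.
    """

    potential: str
    beta: float
    lag: float
    dt: float
    M: int
    r: int
    eval_points: dict
    observables: dict = dc_field(default_factory=lambda: {"mode": "random"})
    potential_params: dict = dc_field(default_factory=dict)
    r_out: int | None = None  # defaults to r
    sigma: float | str = "auto"
    cutoff: float | str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        missing = {"potential", "beta", "lag", "dt", "M", "r", "eval_points"} - set(d)
        if missing:
            raise ConfigurationError(f"missing config keys: {sorted(missing)}")
        return cls(**dict(d))

    def resolved(self) -> dict:
        """JSON-serializable copy with every default filled in."""
        return {
            "potential": self.potential,
            "potential_params": dict(self.potential_params),
            "beta": self.beta,
            "lag": self.lag,
            "dt": self.dt,
            "M": self.M,
            "r": self.r,
            "r_out": self.r_out if self.r_out is not None else self.r,
            "eval_points": dict(self.eval_points),
            "observables": dict(self.observables),
            "sigma": self.sigma,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "scheme": "euler-maruyama",
        }

    def build_potential(self) -> Potential:
        return make_potential(self.potential, self.potential_params)

    def integrator(self, stream: int = _STREAM_BURSTS) -> IntegratorSpec:
        return IntegratorSpec(dt=self.dt, beta=self.beta, seed=derive_seed(self.seed, stream))


@dataclass
class ReactionCoordinateField:
    """xi_bar on the evaluation points, with all intermediates retained."""

    eval_points: np.ndarray  # (ell, n)
    rc_values: np.ndarray  # (ell, r_out)
    embedded: EmbeddedCloud
    dm_model: DiffusionMapModel
    config: PipelineConfig

    @property
    def fallback_rc(self) -> np.ndarray:
        """The (2r+1)-dimensional coordinate without manifold learning."""
        return self.embedded.points


def generate_eval_points(config: PipelineConfig) -> np.ndarray:
    """Evaluation points per the config's generation mode.

    Grid mode returns the tensor grid of vertices (corners included);
    subsample mode simulates a trajectory and subsamples it uniformly
    without replacement.
    """
    spec = config.eval_points
    mode = spec.get("mode")
    if mode == "grid":
        lower = np.atleast_1d(np.asarray(spec["lower"], dtype=float))
        upper = np.atleast_1d(np.asarray(spec["upper"], dtype=float))
        counts = np.atleast_1d(np.asarray(spec["counts"], dtype=int))
        if np.prod(counts) > MAX_GRID_POINTS:
            raise ConfigurationError(
                "grid would exceed 1e7 points; use a trajectory subsample instead"
            )
        axes = [np.linspace(a, b, c) for a, b, c in zip(lower, upper, counts)]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=-1)
    if mode == "subsample":
        pot = config.build_potential()
        ispec = config.integrator(_STREAM_TRAJECTORY)
        traj = simulate_trajectory(
            pot, ispec, spec["x0"], spec["total_time"], spec["stride"]
        )
        return traj.subsample(int(spec["count"]), derive_seed(config.seed, _STREAM_SUBSAMPLE))
    if mode == "explicit":
        return np.atleast_2d(np.asarray(spec["points"], dtype=float))
    raise ConfigurationError(f"unknown eval_points mode {mode!r}")


def resolve_observables(config: PipelineConfig, n: int) -> ObservableSet:
    spec = config.observables
    mode = spec.get("mode", "random")
    if mode == "explicit":
        return ObservableSet(
            n=n, r=config.r, kind="linear",
            coefficients=np.asarray(spec["coefficients"], dtype=float),
        )
    if mode == "random":
        return draw_linear_observables(
            n, config.r, derive_seed(config.seed, _STREAM_OBSERVABLES),
            low=float(spec.get("low", -1.0)), high=float(spec.get("high", 1.0)),
        )
    raise ConfigurationError(f"unknown observables mode {mode!r}")


def compute_rc(config: PipelineConfig) -> ReactionCoordinateField:
    """Run the full five-stage pipeline for the given config."""
    pot = config.build_potential()
    points = generate_eval_points(config)
    if points.shape[1] != pot.dimension:
        raise ConfigurationError(
            f"evaluation points have dimension {points.shape[1]}, "
            f"potential {config.potential} has {pot.dimension}"
        )
    obs = resolve_observables(config, pot.dimension)
    cloud = embed_points(pot, config.integrator(), obs, points, config.lag, config.M)
    r_out = config.r_out if config.r_out is not None else config.r
    model = fit_diffusion_map(
        cloud.points, sigma=config.sigma, cutoff=config.cutoff, r_out=r_out
    )
    return ReactionCoordinateField(
        eval_points=points,
        rc_values=model.psi_train,
        embedded=cloud,
        dm_model=model,
        config=config,
    )


def extend_rc(
    field: ReactionCoordinateField, query_points, method: str = "nearest"
) -> np.ndarray:
    """xi_bar at new state-space points.

    ``nearest`` copies the value of the nearest evaluation point (exact
    ties resolved to the lowest index); ``nystrom`` launches fresh bursts
    at the queries, embeds them with the same observables, and evaluates
    the diffusion map out of sample.
    """
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if method == "nearest":
        tree = cKDTree(field.eval_points)
        k = min(2, len(field.eval_points))
        dist, idx = tree.query(q, k=k)
        if k == 2:
            nearest = np.where(
                np.isclose(dist[:, 0], dist[:, 1], rtol=0, atol=0)
                & (dist[:, 0] == dist[:, 1]),
                np.minimum(idx[:, 0], idx[:, 1]),
                idx[:, 0],
            )
        else:
            nearest = np.atleast_1d(idx).ravel()
        return field.rc_values[nearest]
    if method == "nystrom":
        cfg = field.config
        if cfg is None:
            raise ConfigurationError("nystrom extension needs the pipeline config")
        pot = cfg.build_potential()
        spec = cfg.integrator(_STREAM_NYSTROM)
        ensemble = burst_endpoints(pot, spec, q, cfg.lag, cfg.M)
        cloud = mc_koopman(ensemble, field.embedded.observables)
        return evaluate_psi(field.dm_model, cloud.points)
    raise ConfigurationError(f"unknown extension method {method!r}")


def compare_coordinates(
    trajectory: Trajectory,
    candidates: Mapping[str, Callable | np.ndarray],
    n_bins: int,
    lag: float,
    m: int,
    reference: SpectrumResult | None = None,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """Projected dominant spectra of several candidate coordinates.

    Each candidate is a callable on the (N, n) state array or a
    precomputed (N,) / (N, r) value array.  Returns one row per candidate
    with the top-m eigenvalues and, when a full-space reference spectrum
    is given, the absolute eigenvalue errors.
    """
    rows = {}
    for name, cand in candidates.items():
        vals = cand(trajectory.states) if callable(cand) else np.asarray(cand)
        op = ulam_projected(trajectory, vals, n_bins, lag, symmetrize=symmetrize)
        spec_m = min(m, op.n_states - 1)
        res = spectrum(op, spec_m)
        row = {f"lambda_{i}": res.eigenvalues[i] for i in range(spec_m)}
        if reference is not None:
            for i in range(min(spec_m, len(reference.eigenvalues))):
                row[f"abs_err_{i}"] = abs(res.eigenvalues[i] - reference.eigenvalues[i])
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
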