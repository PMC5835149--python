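"""Serialization: HDF5 containers for arrays, delimited text for small data.

Every writer stores enough metadata (seed, dt, beta, lag, sigma, ...) to
reconstruct the producing object; text round-trips use 17 significant
digits so values survive unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .embedding import EmbeddedCloud, ObservableSet
from .manifold_learning import DiffusionMapModel
from .sampler import BurstEnsemble, IntegratorSpec, Trajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_ensemble",
    "load_ensemble",
    "save_cloud",
    "load_cloud",
    "cloud_to_csv",
    "save_dmap",
    "load_dmap",
    "write_manifest",
]

_FMT = "%.17g"


def _spec_attrs(g, spec: IntegratorSpec):
    g.attrs["dt"] = spec.dt
    g.attrs["beta"] = spec.beta
    g.attrs["seed"] = spec.seed
    g.attrs["scheme"] = spec.scheme


def _spec_from(g) -> IntegratorSpec:
    return IntegratorSpec(
        dt=float(g.attrs["dt"]), beta=float(g.attrs["beta"]),
        seed=int(g.attrs["seed"]), scheme=str(g.attrs["scheme"]),
    )


def save_trajectory(path, traj: Trajectory):
    with h5py.File(path, "w") as f:
        g = f.create_group("trajectory")
        g.create_dataset("states", data=traj.states)
        g.attrs["stride"] = traj.stride
        _spec_attrs(g, traj.integrator)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        return Trajectory(g["states"][...], float(g.attrs["stride"]), _spec_from(g))


def save_ensemble(path, ens: BurstEnsemble):
    with h5py.File(path, "w") as f:
        g = f.create_group("bursts")
        g.create_dataset("start_points", data=ens.start_points)
        g.create_dataset("endpoints", data=ens.endpoints)
        g.attrs["lag"] = ens.lag
        _spec_attrs(g, ens.integrator)


def load_ensemble(path) -> BurstEnsemble:
    with h5py.File(path, "r") as f:
        g = f["bursts"]
        return BurstEnsemble(
            g["start_points"][...], g["endpoints"][...],
            float(g.attrs["lag"]), _spec_from(g),
        )


def save_cloud(path, cloud: EmbeddedCloud):
    with h5py.File(path, "w") as f:
        g = f.create_group("cloud")
        g.create_dataset("points", data=cloud.points)
        g.create_dataset("start_points", data=cloud.start_points)
        g.create_dataset("mc_stderr", data=cloud.mc_stderr)
        g.attrs["lag"] = cloud.lag
        g.attrs["M"] = cloud.M
        obs = cloud.observables
        g.attrs["obs_kind"] = obs.kind
        g.attrs["obs_r"] = obs.r
        if obs.kind == "linear":
            g.create_dataset("obs_coefficients", data=obs.coefficients)


def load_cloud(path) -> EmbeddedCloud:
    with h5py.File(path, "r") as f:
        g = f["cloud"]
        start = g["start_points"][...]
        obs = ObservableSet(
            n=start.shape[1], r=int(g.attrs["obs_r"]), kind=str(g.attrs["obs_kind"]),
            coefficients=g["obs_coefficients"][...] if "obs_coefficients" in g else None,
        )
        return EmbeddedCloud(
            points=g["points"][...], start_points=start,
            mc_stderr=g["mc_stderr"][...], observables=obs,
            lag=float(g.attrs["lag"]), M=int(g.attrs["M"]),
        )


def cloud_to_csv(path, cloud: EmbeddedCloud):
    """Delimited text: start coordinates, embedded coordinates, stderr."""
    n, k = cloud.start_points.shape[1], cloud.points.shape[1]
    cols = (
        [f"x{j}" for j in range(n)]
        + [f"z{j}" for j in range(k)]
        + [f"stderr{j}" for j in range(k)]
    )
    df = pd.DataFrame(
        np.hstack([cloud.start_points, cloud.points, cloud.mc_stderr]), columns=cols
    )
    df.to_csv(path, index=False, float_format=_FMT)


def save_dmap(path, model: DiffusionMapModel):
    with h5py.File(path, "w") as f:
        g = f.create_group("dmap")
        g.create_dataset("train_points", data=model.train_points)
        g.create_dataset("eigenvalues", data=model.eigenvalues)
        g.create_dataset("eigenvectors", data=model.eigenvectors)
        g.create_dataset("row_sums", data=model.row_sums)
        g.attrs["sigma"] = model.sigma
        g.attrs["cutoff"] = np.nan if model.cutoff is None else model.cutoff
        g.attrs["r_out"] = model.r_out


def load_dmap(path) -> DiffusionMapModel:
    with h5py.File(path, "r") as f:
        g = f["dmap"]
        cutoff = float(g.attrs["cutoff"])
        return DiffusionMapModel(
            train_points=g["train_points"][...],
            sigma=float(g.attrs["sigma"]),
            cutoff=None if np.isnan(cutoff) else cutoff,
            eigenvalues=g["eigenvalues"][...],
            eigenvectors=g["eigenvectors"][...],
            r_out=int(g.attrs["r_out"]),
            row_sums=g["row_sums"][...],
        )


def write_manifest(path, config_resolved: dict, extra: dict | None = None):
    """JSON run manifest: resolved config, seeds and package versions."""
    import scipy

    from . import __version__

    doc = {
        "config": config_resolved,
        "versions": {
            "tmrc": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
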