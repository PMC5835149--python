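"""Transfer-operator numerics on box partitions and reaction-coordinate bins.

The validation side of the package: the dominant spectrum of the lag-t
transfer operator is estimated by Ulam's method (transition counting over a
box partition of state space, or over bins of a scalar/vector reaction
coordinate, which realizes the coordinate-projected operator empirically),
or deterministically from a finite-difference discretization of the
generator L = -grad V . grad + beta^-1 Laplace with no-flux boundaries.
Implied timescales follow from t_i = -t / log(lambda_i).

A projected operator can only lose spectrum: if the residual of a dominant
eigenfunction phi under the level-set conditional expectation P_xi has norm
eps, the projected operator retains an eigenvalue within
eps / sqrt(1 - eps^2) of the original one.  :func:`lemma_oracle` checks
that bound on explicit matrices, and :func:`projection_error` estimates eps
from samples by within-bin averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as splinalg

from .errors import (
    DegenerateCoordinateError,
    NumericalError,
    ValidationError,
)
from .potentials import Potential
from .sampler import Trajectory

__all__ = [
    "BoxPartition",
    "UlamOperator",
    "SpectrumResult",
    "ulam_full",
    "ulam_projected",
    "spectrum",
    "generator_spectrum",
    "msm_core_matrix",
    "projection_error",
    "lemma_oracle",
    "random_lemma_instance",
]


@dataclass(frozen=True)
class BoxPartition:
    """Uniform half-open box partition of a bounded axis-aligned domain."""

    lower: np.ndarray
    upper: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        ct = np.atleast_1d(np.asarray(self.counts, dtype=int))
        if not (lo.shape == hi.shape == ct.shape):
            raise ValidationError("lower/upper/counts must have matching shapes")
        if np.any(hi <= lo) or np.any(ct < 1):
            raise ValidationError("need upper > lower and counts >= 1")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "counts", ct)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.counts))

    @property
    def dimension(self) -> int:
        return len(self.counts)

    def index(self, points) -> np.ndarray:
        """Flat cell index per point; -1 for points outside the domain."""
        x = np.atleast_2d(np.asarray(points, dtype=float))
        frac = (x - self.lower) / (self.upper - self.lower)
        ij = np.floor(frac * self.counts).astype(int)
        # the closed upper face belongs to the last cell
        on_top = (x == self.upper) & (ij == self.counts)
        ij[on_top] -= 1
        inside = np.all((ij >= 0) & (ij < self.counts), axis=1)
        flat = np.ravel_multi_index(
            tuple(np.clip(ij, 0, self.counts - 1).T), tuple(self.counts)
        )
        return np.where(inside, flat, -1)

    def centers(self) -> np.ndarray:
        axes = [
            self.lower[d] + (np.arange(self.counts[d]) + 0.5) * (self.upper[d] - self.lower[d]) / self.counts[d]
            for d in range(self.dimension)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=-1)


@dataclass
class UlamOperator:
    """Row-stochastic transition matrix over occupied cells."""

    counts: np.ndarray  # (N, N) pair counts (after optional symmetrization)
    transition_matrix: np.ndarray  # (N, N) row-stochastic
    lag: float
    symmetrized: bool
    active_cells: np.ndarray  # indices into the full partition / bin grid
    partition: BoxPartition | None = None
    n_dropped: int = 0  # sample pairs outside the domain / in empty bins
    flagged_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)

    @property
    def occupation(self) -> np.ndarray:
        """Cell-occupation distribution (source counts, normalized)."""
        w = self.counts.sum(axis=1)
        return w / w.sum()


@dataclass
class SpectrumResult:
    """Dominant eigenvalues, implied timescales and the spectral-gap count."""

    eigenvalues: np.ndarray  # descending (by real part), lambda_0 ~ 1 first
    eigenvectors: np.ndarray  # (N, m)
    implied_timescales: np.ndarray  # t_i = -lag/log(lambda_i); inf / nan edges
    lag: float
    dominant_count: int


def _count_matrix(src, dst, symmetrize):
    """Dense pair-count matrix restricted to occupied cells."""
    occupied = np.unique(np.concatenate([src, dst]))
    remap = -np.ones(occupied.max() + 1 if occupied.size else 1, dtype=int)
    remap[occupied] = np.arange(len(occupied))
    a, b = remap[src], remap[dst]
    n = len(occupied)
    c = np.zeros((n, n))
    np.add.at(c, (a, b), 1.0)
    if symmetrize:
        c = 0.5 * (c + c.T)
    return c, occupied


def _row_normalize(c):
    rows = c.sum(axis=1)
    flagged = np.flatnonzero(rows == 0)
    p = np.array(c)
    for i in flagged:  # self-loop keeps the matrix stochastic
        p[i, i] = 1.0
    p = p / p.sum(axis=1, keepdims=True)
    return p, flagged


def _lagsteps(lag, stride):
    n = lag / stride
    if abs(n - round(n)) > 1e-8 * max(1.0, n):
        raise ValidationError(f"lag={lag} is not a multiple of the stride {stride}")
    n = int(round(n))
    if n < 1:
        raise ValidationError("lag must be at least one stride")
    return n


def ulam_full(
    trajectory: Trajectory,
    partition: BoxPartition,
    lag: float,
    symmetrize: bool = False,
) -> UlamOperator:
    """Ulam transition counting of a trajectory over a box partition.

    Every sliding-window pair (x_s, x_{s+lag/stride}) with both states
    inside the domain contributes one count; out-of-domain pairs are
    dropped (their number is recorded).
    """
    if len(trajectory) == 0:
        raise ValidationError("empty trajectory")
    L = _lagsteps(lag, trajectory.stride)
    if len(trajectory) <= L:
        raise ValidationError("trajectory shorter than one lag")
    cell = partition.index(trajectory.states)
    a, b = cell[:-L], cell[L:]
    keep = (a >= 0) & (b >= 0)
    if not np.any(keep):
        raise ValidationError("no trajectory pairs inside the partition domain")
    c, occupied = _count_matrix(a[keep], b[keep], symmetrize)
    p, flagged = _row_normalize(c)
    return UlamOperator(
        counts=c,
        transition_matrix=p,
        lag=float(lag),
        symmetrized=symmetrize,
        active_cells=occupied,
        partition=partition,
        n_dropped=int((~keep).sum()),
        flagged_rows=flagged,
    )


def ulam_projected(
    trajectory: Trajectory,
    rc_values,
    n_bins: int,
    lag: float,
    symmetrize: bool = False,
) -> UlamOperator:
    """Ulam counting in uniform bins of a reaction coordinate.

    ``rc_values`` holds the coordinate at every trajectory state (shape
    (N,) or (N, r)); each component is binned into ``n_bins`` equal
    intervals over its range (a product grid for r >= 2, with empty cells
    dropped by the occupied-cell restriction).
    """
    rc = np.asarray(rc_values, dtype=float)
    if rc.ndim == 1:
        rc = rc[:, None]
    if len(rc) != len(trajectory):
        raise ValidationError("rc_values must align 1:1 with trajectory states")
    if n_bins < 2:
        raise ValidationError("need n_bins >= 2")
    lo, hi = rc.min(axis=0), rc.max(axis=0)
    if np.any(hi - lo <= 0):
        raise DegenerateCoordinateError("a reaction-coordinate component is constant")
    L = _lagsteps(lag, trajectory.stride)
    idx = np.minimum(((rc - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    flat = np.ravel_multi_index(tuple(idx.T), (n_bins,) * rc.shape[1])
    c, occupied = _count_matrix(flat[:-L], flat[L:], symmetrize)
    p, flagged = _row_normalize(c)
    return UlamOperator(
        counts=c,
        transition_matrix=p,
        lag=float(lag),
        symmetrized=symmetrize,
        active_cells=occupied,
        partition=None,
        n_dropped=0,
        flagged_rows=flagged,
    )


def _dominant_count(vals: np.ndarray) -> int:
    gaps = vals[:-1] - vals[1:]
    return int(np.argmax(gaps)) + 1 if len(gaps) else 1


def _timescales(vals: np.ndarray, lag: float) -> np.ndarray:
    ts = np.full(len(vals), np.nan)
    for i, lam in enumerate(vals):
        if lam >= 1 - 1e-12:
            ts[i] = np.inf
        elif lam > 0:
            ts[i] = -lag / np.log(lam)
    return ts


def spectrum(op: UlamOperator, m: int) -> SpectrumResult:
    """Top-m eigenvalues (by real part) of the transition matrix.

    Symmetrized operators are reversible with respect to their occupation
    distribution, so their spectrum is computed through the exactly
    symmetric similar matrix and is real by construction.
    """
    N = op.n_states
    if m >= N:
        raise ValidationError(f"m must be < number of states ({N})")
    P = op.transition_matrix
    try:
        if op.symmetrized:
            pi = op.occupation
            s = np.sqrt(np.maximum(pi, 1e-300))
            S = (s[:, None] * P) / s[None, :]
            S = 0.5 * (S + S.T)
            if N > 2000:
                vals, vecs = splinalg.eigsh(sparse.csr_matrix(S), k=m, which="LA")
            else:
                vals, vecs = np.linalg.eigh(S)
            order = np.argsort(vals)[::-1][:m]
            vals, vecs = vals[order], vecs[:, order] / s[:, None]
        else:
            if N > 2000:
                vals, vecs = splinalg.eigs(sparse.csr_matrix(P.T), k=m, which="LR")
            else:
                vals, vecs = np.linalg.eig(P.T)
            order = np.argsort(vals.real)[::-1][:m]
            vals, vecs = vals[order].real, vecs[:, order].real
    except splinalg.ArpackNoConvergence as exc:  # pragma: no cover
        raise NumericalError(
            "eigensolver did not converge; retry with a smaller m, a dense "
            "solve, or a longer trajectory"
        ) from exc
    return SpectrumResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        implied_timescales=_timescales(vals, op.lag),
        lag=op.lag,
        dominant_count=_dominant_count(vals),
    )


def generator_spectrum(
    potential: Potential,
    beta: float,
    lower,
    upper,
    counts,
    lag: float,
    m: int = 10,
) -> SpectrumResult:
    """Deterministic reference spectrum from the discretized generator.

    The generator L = -grad V . grad + beta^-1 Laplace is discretized as a
    nearest-neighbor jump process with rates
    k_ij = exp(-beta (V_j - V_i)/2) / (beta h^2) on a uniform grid with
    no-flux boundaries.  The chain is reversible for the Boltzmann weights,
    its rate matrix is similar to a symmetric matrix with constant
    off-diagonal entries, and the transfer-operator eigenvalues at lag t
    are exp(kappa_i t).  Eigenvectors are returned in Koopman (observable)
    normalization, orthonormal under the Boltzmann weights.
    """
    part = BoxPartition(lower, upper, counts)
    axes = [
        np.linspace(part.lower[d], part.upper[d], part.counts[d])
        for d in range(part.dimension)
    ]
    h = [ax[1] - ax[0] for ax in axes]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    V = potential(pts)
    shape = tuple(part.counts)
    N = pts.shape[0]
    idx = np.arange(N).reshape(shape)
    rows, cols, offs = [], [], []
    for d in range(part.dimension):
        lo = np.moveaxis(idx, d, 0)[:-1].ravel()
        hi = np.moveaxis(idx, d, 0)[1:].ravel()
        rows += [lo, hi]
        cols += [hi, lo]
        offs += [np.full(lo.shape, 1.0 / (beta * h[d] ** 2))] * 2
    rows, cols = np.concatenate(rows), np.concatenate(cols)
    offs = np.concatenate(offs)
    S = sparse.coo_matrix((offs, (rows, cols)), shape=(N, N)).tocsr()
    diag = np.zeros(N)
    np.add.at(diag, rows, offs * np.exp(-beta * (V[cols] - V[rows]) / 2))
    S = S - sparse.diags(diag)
    kappa, vecs = splinalg.eigsh(S, k=m, which="LA")
    order = np.argsort(kappa)[::-1]
    kappa, vecs = kappa[order], vecs[:, order]
    kappa = np.minimum(kappa, 0.0)
    vals = np.exp(kappa * lag)
    # back-transform: S = diag(sqrt(pi)) Q diag(1/sqrt(pi)) with pi ~ e^{-beta V}
    phi = vecs * np.exp(beta * (V[:, None] - V.min()) / 2)
    w = np.exp(-beta * (V - V.min()))
    phi /= np.sqrt(np.sum(w[:, None] * phi**2, axis=0))
    return SpectrumResult(
        eigenvalues=vals,
        eigenvectors=phi,
        implied_timescales=_timescales(vals, lag),
        lag=float(lag),
        dominant_count=_dominant_count(vals),
    )


def msm_core_matrix(trajectory: Trajectory, cores, lag: float) -> np.ndarray:
    """Core-to-core transition probabilities at the given lag.

    ``cores`` is a list of predicates mapping an (N, n) state array to a
    boolean mask; they must be pairwise disjoint.  Pairs whose start or end
    lies outside every core are excluded.  The caller is responsible for
    supplying an equilibrated trajectory.
    """
    L = _lagsteps(lag, trajectory.stride)
    states = trajectory.states
    label = -np.ones(len(states), dtype=int)
    for i, core in enumerate(cores):
        mask = np.asarray(core(states), dtype=bool)
        if np.any(label[mask] >= 0):
            raise ValidationError("cores are not pairwise disjoint")
        label[mask] = i
    for i in range(len(cores)):
        if not np.any(label == i):
            raise NumericalError(f"core {i} is never visited by the trajectory")
    a, b = label[:-L], label[L:]
    keep = (a >= 0) & (b >= 0)
    k = len(cores)
    c = np.zeros((k, k))
    np.add.at(c, (a[keep], b[keep]), 1.0)
    rows = c.sum(axis=1)
    if np.any(rows == 0):
        bad = int(np.flatnonzero(rows == 0)[0])
        raise NumericalError(f"core {bad} has no observed transitions at this lag")
    return c / rows[:, None]


def projection_error(values, rc_values, n_bins: int, weights=None) -> float:
    """Empirical norm of the residual of the level-set projection.

    P_xi f is estimated by the weighted mean of ``values`` within each
    uniform bin of the reaction coordinate; the return value is the
    weighted root-mean-square of f - P_xi f, i.e. the projection error
    that enters the eigenvalue perturbation bound.
    """
    f = np.asarray(values, dtype=float).ravel()
    rc = np.asarray(rc_values, dtype=float)
    if rc.ndim == 1:
        rc = rc[:, None]
    if len(f) != len(rc):
        raise ValidationError("values and rc_values must align")
    w = np.ones(len(f)) if weights is None else np.asarray(weights, dtype=float)
    if np.unique(rc, axis=0).shape[0] < n_bins:
        raise ValidationError("n_bins exceeds the number of distinct rc values")
    lo, hi = rc.min(axis=0), rc.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    idx = np.minimum(((rc - lo) / span * n_bins).astype(int), n_bins - 1)
    flat = np.ravel_multi_index(tuple(idx.T), (n_bins,) * rc.shape[1])
    wsum = np.bincount(flat, weights=w)
    fsum = np.bincount(flat, weights=w * f)
    mean = np.where(wsum > 0, fsum / np.maximum(wsum, 1e-300), 0.0)
    resid = f - mean[flat]
    return float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))


def lemma_oracle(T, Q, u) -> dict:
    """Check the projected-eigenvalue perturbation bound on matrices.

    For a symmetric non-expansive T with unit eigenvector u and an
    orthogonal projection Q, the projected matrix QTQ must have an
    eigenvalue within eps / sqrt(1 - eps^2) of u's eigenvalue, where
    eps = |(I - Q) u|.  Returns eps, the bound, the actual distance to the
    nearest eigenvalue of QTQ, and whether the bound holds (None when
    eps >= 1 makes it vacuous).
    """
    T = np.asarray(T, dtype=float)
    Q = np.asarray(Q, dtype=float)
    u = np.asarray(u, dtype=float).ravel()
    if not np.allclose(T, T.T, atol=1e-10):
        raise ValidationError("T must be symmetric")
    if not (np.allclose(Q @ Q, Q, atol=1e-10) and np.allclose(Q, Q.T, atol=1e-10)):
        raise ValidationError("Q must be an orthogonal projection (Q^2 = Q = Q^T)")
    if np.linalg.norm(T, 2) > 1 + 1e-8:
        raise ValidationError("T must be non-expansive (spectral norm <= 1)")
    if abs(np.linalg.norm(u) - 1) > 1e-8:
        raise ValidationError("u must be a unit vector")
    Tu = T @ u
    lam = float(u @ Tu)
    if np.linalg.norm(Tu - lam * u) > 1e-8:
        raise ValidationError("u is not an eigenvector of T")
    eps = float(np.linalg.norm(u - Q @ u))
    proj_eigs = np.linalg.eigvalsh(Q @ T @ Q)
    dist = float(np.min(np.abs(proj_eigs - lam)))
    if eps >= 1:
        return {"epsilon": eps, "bound": np.inf, "min_eig_dist": dist, "holds": None}
    bound = eps / np.sqrt(1 - eps**2)
    return {
        "epsilon": eps,
        "bound": bound,
        "min_eig_dist": dist,
        "holds": bool(dist < bound + 1e-12),
    }


def random_lemma_instance(dim: int, rng: np.random.Generator):
    """A random (T, Q, u) triple satisfying the oracle's preconditions."""
    A = rng.standard_normal((dim, dim))
    T = 0.5 * (A + A.T)
    T /= np.linalg.norm(T, 2) * (1 + 1e-12)
    vals, vecs = np.linalg.eigh(T)
    u = vecs[:, rng.integers(dim)]
    k = int(rng.integers(1, dim + 1))
    B = rng.standard_normal((dim, k))
    Uq, _ = np.linalg.qr(B)
    Q = Uq @ Uq.T
    return T, Q, u
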