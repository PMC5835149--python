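"""Diffusion-map parametrization of the embedded transition manifold.

Given the embedded cloud {z_i} in R^(2r+1), a Gaussian kernel similarity
matrix

    W_ij = h(|z_i - z_j|^2 / sigma),    h(u) = exp(-u) * 1_{u <= R},

is formed and normalized in two stages: W~ = D^-1 W D^-1 with D the diagonal
of row sums of W (this removes the sampling-density bias, so the spectrum
approximates the Laplace-Beltrami operator of the manifold rather than of
the density), then P = D~^-1 W~ with D~ the diagonal of row sums of W~.
P is row stochastic and similar to the symmetric matrix
D~^-1/2 W~ D~^-1/2, so its eigenvalues gamma_i are real, gamma_0 = 1 with a
constant eigenvector, and |gamma_i| <= 1.  The diffusion map is

    Psi(z) = (gamma_1 psi_1(z), ..., gamma_r psi_r(z)),

evaluated exactly on training points and by Nystrom extension elsewhere.

The intrinsic-dimension diagnostic estimates how many directions of
variation the cloud actually has; see :func:`dimension_diagnostic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as splinalg
from scipy.spatial import cKDTree

from .errors import DisconnectedGraphError, ValidationError

__all__ = [
    "DiffusionMapModel",
    "fit_diffusion_map",
    "evaluate_psi",
    "dimension_diagnostic",
    "auto_sigma",
]

#: above this size the kernel is truncated and held sparse
DENSE_LIMIT = 5000
#: minimum neighbor count retained by the automatic cutoff
MIN_NEIGHBORS = 32


@dataclass
class DiffusionMapModel:
    """Fitted kernel eigen-decomposition with out-of-sample data."""

    train_points: np.ndarray  # (ell, d)
    sigma: float
    cutoff: float | None  # R, in squared-distance/sigma units
    eigenvalues: np.ndarray  # (r_out+1,), descending, gamma_0 = 1
    eigenvectors: np.ndarray  # (ell, r_out+1), psi columns
    r_out: int
    row_sums: np.ndarray  # D_ii of the first normalization stage

    @property
    def psi_train(self) -> np.ndarray:
        """Psi on the training cloud: columns gamma_j * psi_j, j = 1..r_out."""
        return self.eigenvalues[1:] * self.eigenvectors[:, 1:]


def auto_sigma(points: np.ndarray, max_sample: int = 2048) -> float:
    """Median of nonzero squared pairwise distances divided by ln 2.

    With this scale the kernel value at the median distance is 1/2.  For
    large clouds the median is taken over a fixed-seed subsample.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) > max_sample:
        idx = np.random.default_rng(0).choice(len(pts), max_sample, replace=False)
        pts = pts[idx]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    nz = d2[d2 > 0]
    if nz.size == 0:
        raise ValidationError("all points coincide; no kernel scale")
    return float(np.median(nz) / np.log(2.0))


def _sign_fix(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _tie_break(vals: np.ndarray, vecs: np.ndarray, tol: float = 1e-12):
    """Order eigenvectors within numerically equal eigenvalues
    lexicographically by their first differing entry."""
    order = np.arange(len(vals))
    i = 0
    while i < len(vals):
        j = i + 1
        while j < len(vals) and abs(vals[j] - vals[i]) <= tol:
            j += 1
        if j - i > 1:
            block = sorted(range(i, j), key=lambda k: tuple(vecs[:, order[k]]))
            order[i:j] = order[block]
        i = j
    return vals, vecs[:, order]


def fit_diffusion_map(
    points,
    sigma: float | str = "auto",
    cutoff: float | str | None = None,
    r_out: int = 2,
) -> DiffusionMapModel:
    """Fit the two-stage-normalized diffusion map on ``points``.

    Parameters
    ----------
    points : (ell, d) array
    sigma : positive float or "auto"
        Kernel scale; "auto" uses :func:`auto_sigma`.
    cutoff : positive float, "auto", or None
        Truncation radius R of the kernel argument (squared distance over
        sigma).  None keeps the dense kernel for ell <= 5000; larger clouds
        fall back to an automatic cutoff keeping at least 32 neighbors.
    r_out : number of nontrivial eigenpairs to retain
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValidationError("points must be a 2-D array")
    ell = len(pts)
    if ell < r_out + 1:
        raise ValidationError(f"need at least r_out+1={r_out + 1} points, got {ell}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points must be finite")
    sig = auto_sigma(pts) if sigma == "auto" else float(sigma)
    if not sig > 0:
        raise ValidationError("sigma must be positive")
    if cutoff is None and ell > DENSE_LIMIT:
        cutoff = "auto"

    if cutoff is None:
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        W = np.exp(-d2 / sig)
        R = None
        off = W - np.diag(np.diag(W))
        isolated = np.flatnonzero(off.sum(axis=1) < 1e-300)
    else:
        tree = cKDTree(pts)
        if cutoff == "auto":
            k = min(MIN_NEIGHBORS + 1, ell)
            dk, _ = tree.query(pts, k=k)
            R = float(np.max(dk[:, -1]) ** 2 / sig)
        else:
            R = float(cutoff)
        radius = float(np.sqrt(R * sig))
        W = tree.sparse_distance_matrix(tree, radius, output_type="coo_matrix")
        W = sparse.coo_matrix(
            (np.exp(-(W.data**2) / sig), (W.row, W.col)), shape=(ell, ell)
        ).tocsr()
        W = W + sparse.identity(ell, format="csr")  # self-similarity h(0) = 1
        counts = np.diff(W.indptr)
        isolated = np.flatnonzero(counts <= 1)
    if isolated.size:
        raise DisconnectedGraphError(isolated)

    if R is None:
        D = W.sum(axis=1)
        Wt = W / (D[:, None] * D[None, :])
        Dt = Wt.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(Dt)
        S = inv_sqrt[:, None] * Wt * inv_sqrt[None, :]
        S = 0.5 * (S + S.T)
        k = r_out + 1
        if ell <= 2000:
            vals, vecs = np.linalg.eigh(S)
            vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
        else:
            vals, vecs = splinalg.eigsh(S, k=k, which="LA")
            order = np.argsort(vals)[::-1]
            vals, vecs = vals[order], vecs[:, order]
    else:
        D = np.asarray(W.sum(axis=1)).ravel()
        Dinv = sparse.diags(1.0 / D)
        Wt = Dinv @ W @ Dinv
        Dt = np.asarray(Wt.sum(axis=1)).ravel()
        half = sparse.diags(1.0 / np.sqrt(Dt))
        S = half @ Wt @ half
        S = 0.5 * (S + S.T)
        vals, vecs = splinalg.eigsh(S, k=r_out + 1, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        Dt = np.asarray(Dt)

    vals = np.clip(vals, -1.0, 1.0)
    vals, vecs = _tie_break(vals, vecs)
    psi = vecs / np.sqrt(np.asarray(Dt)).reshape(-1, 1)
    psi = _sign_fix(psi)
    return DiffusionMapModel(
        train_points=pts,
        sigma=sig,
        cutoff=R,
        eigenvalues=vals,
        eigenvectors=psi,
        r_out=r_out,
        row_sums=np.asarray(D).ravel(),
    )


def evaluate_psi(model: DiffusionMapModel, query_points) -> np.ndarray:
    """Psi at arbitrary points by Nystrom extension.

    Training points reproduce their stored values (the kernel row equals
    the corresponding row of the training kernel).  A query whose kernel
    row is entirely below the cutoff raises an isolated-query error.
    """
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if q.shape[1] != model.train_points.shape[1]:
        raise ValidationError("query dimension does not match training points")
    out = np.empty((len(q), model.r_out))
    for lo in range(0, len(q), 4096):  # bound the q x ell kernel block
        block = q[lo : lo + 4096]
        d2 = np.sum((block[:, None, :] - model.train_points[None, :, :]) ** 2, axis=-1)
        u = d2 / model.sigma
        w = np.exp(-u)
        if model.cutoff is not None:
            w[u > model.cutoff] = 0.0
        rows = w.sum(axis=1)
        dead = np.flatnonzero(rows <= 0)
        if dead.size:
            raise DisconnectedGraphError(
                lo + dead,
                "queries beyond the kernel cutoff of every training point: "
                f"{(lo + dead)[:20]}",
            )
        wt = w / (rows[:, None] * model.row_sums[None, :])
        P = wt / wt.sum(axis=1, keepdims=True)
        # standard Nystrom gives psi_j(q) = P_q . psi_j / gamma_j; multiplying
        # by gamma_j yields the diffusion-map component directly.
        out[lo : lo + 4096] = P @ model.eigenvectors[:, 1:]
    return out


def _thin_closed_curve(points: np.ndarray, n_sectors: int = 16, thin: float = 0.2):
    """Detect a thin closed curve in the leading-2 PCA plane.

    Returns (is_loop, thickness): thickness is the mean per-angular-sector
    radial coefficient of variation; a loop needs every sector occupied and
    thickness below ``thin``.
    """
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    p = c @ vt[:2].T
    p = p - p.mean(axis=0)
    theta = np.arctan2(p[:, 1], p[:, 0])
    radius = np.hypot(p[:, 0], p[:, 1])
    edges = np.linspace(-np.pi, np.pi, n_sectors + 1)
    which = np.clip(np.digitize(theta, edges) - 1, 0, n_sectors - 1)
    counts = np.bincount(which, minlength=n_sectors)
    if counts.min() == 0:
        return False, np.inf
    cvs = []
    for b in range(n_sectors):
        rb = radius[which == b]
        if len(rb) >= 4 and rb.mean() > 0:
            cvs.append(rb.std() / rb.mean())
    if len(cvs) < n_sectors // 2:
        return False, np.inf
    thickness = float(np.mean(cvs))
    return thickness < thin, thickness


def dimension_diagnostic(model: DiffusionMapModel) -> dict:
    """Estimate the intrinsic dimension of the training cloud.

    Two-stage rule:

    1. *Closed-curve detection.*  A thin closed curve (full angular coverage
       and small per-sector radial thickness in the leading-2 PCA plane) is
       one-dimensional regardless of its spectral signature -- closed
       1-manifolds produce near-degenerate eigenvalue pairs, not a single
       dominant eigenvalue, so a purely spectral count would overshoot.
    2. *Weyl-law slope.*  Otherwise, for a d-dimensional manifold the k-th
       Laplacian eigenvalue grows like k^(2/d), so -log(gamma_k) ~ k^(2/d)
       in the heat-kernel regime; the slope s of log(-log gamma_k) against
       log k over the significant modes (gamma_k >= 0.05 gamma_1) gives
       d = 2/s, rounded to the nearest integer.

    The near-degenerate-pair caveat (gamma_1 and gamma_2 within 10%) is
    always reported: it signals circle-like topology for which the
    parametrization needs one more component than the intrinsic dimension.
    """
    nt = model.eigenvalues[1:]
    if len(nt) < 3:
        raise ValidationError("dimension diagnostic needs r_out >= 3")
    nt = np.maximum(nt, 1e-300)
    ratios = (nt[1:] / nt[:-1]).tolist()
    near_pair = (nt[0] - nt[1]) / nt[0] < 0.10

    is_loop, thickness = _thin_closed_curve(model.train_points)
    K = int(np.sum(nt >= 0.05 * nt[0]))
    if is_loop:
        dim, weyl = 1, None
    elif K <= 1:
        dim, weyl = 1, None
    else:
        k = np.arange(1, K + 1)
        y = np.log(-np.log(np.minimum(nt[:K], 1 - 1e-15)))
        slope = np.polyfit(np.log(k), y, 1)[0]
        weyl = 2.0 / max(slope, 1e-6)
        dim = max(1, int(round(weyl)))
    return {
        "spectral_ratios": ratios,
        "suggested_dim": dim,
        "near_degenerate_pair": bool(near_pair),
        "closed_curve": bool(is_loop),
        "loop_thickness": thickness,
        "weyl_dimension": weyl,
    }
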