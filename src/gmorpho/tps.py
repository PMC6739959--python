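"""Thin-plate spline interpolation for 2D landmark configurations.

The TPS map interpolates one landmark configuration (the *source*, usually a
sample consensus) onto another (the *target*) as the sum of an affine map and
a superposition of radial basis kernels ``U(r) = r^2 log(r^2)`` centred at the
source landmarks.  Its bending energy quantifies the non-affine part of the
deformation, and the eigenvectors of the bending-energy matrix at a reference
shape (the *partial warps*) give a spatial-scale-ordered orthonormal basis for
non-affine shape variation.

Kernel convention is Bookstein's original ``U = r^2 log r^2``; constant
factors cancel in any log-log regression on the eigenvalues but the choice is
fixed here so bending energies are bit-stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TpsModel",
    "BendingSpectrum",
    "fit_tps",
    "evaluate_tps",
    "bending_energy",
    "bending_energy_matrix",
    "bending_spectrum",
    "partial_warp_scores",
    "jacobian_logdet_field",
    "make_grid",
]


class DegenerateReferenceError(ValueError):
    """Raised when source landmarks are collinear/duplicated and the TPS
    system is singular."""


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log(r^2), with the r -> 0 limit set to 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0.0, out, 0.0)


def _kernel_matrix(points: np.ndarray) -> np.ndarray:
    d = points[:, None, :] - points[None, :, :]
    return _kernel(np.einsum("ijk,ijk->ij", d, d))


@dataclass(frozen=True)
class TpsModel:
    """Fitted thin-plate spline map between two k x 2 configurations.

    ``affine`` is a 3 x 2 matrix: row 0 the translation, rows 1-2 the linear
    part, so that the affine image of p is ``[1, px, py] @ affine``.
    ``weights`` (k x 2) are the non-affine kernel coefficients; they sum to
    zero and are orthogonal to the source coordinates (TPS side conditions).
    """

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray
    weights: np.ndarray

    @property
    def k(self) -> int:
        return self.source.shape[0]


def fit_tps(source: np.ndarray, target: np.ndarray) -> TpsModel:
    """Fit the interpolating TPS map sending ``source`` onto ``target``.

    Solves the standard bordered linear system with kernel U(r) = r^2 log r^2.
    Interpolation is exact at the landmarks.

    Raises
    ------
    DegenerateReferenceError
        if the source points are collinear or contain duplicates, which makes
        the system singular.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 2:
        raise ValueError("source and target must both be k x 2 arrays of equal k")
    k = source.shape[0]
    if k < 4:
        raise ValueError("TPS requires at least 4 landmarks in 2D")

    K = _kernel_matrix(source)
    Q = np.column_stack([np.ones(k), source])          # k x 3
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateReferenceError(
            "TPS system singular: source landmarks collinear or duplicated"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise DegenerateReferenceError("TPS solution not finite")
    model = TpsModel(source=source, target=target,
                     weights=sol[:k], affine=sol[k:])
    resid = np.abs(evaluate_tps(model, source) - target).max()
    if resid > 1e-6:
        raise DegenerateReferenceError(
            f"TPS interpolation residual {resid:.3g}: near-singular source"
        )
    return model


def evaluate_tps(model: TpsModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map at arbitrary 2D points (m x 2)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = points[:, None, :] - model.source[None, :, :]
    U = _kernel(np.einsum("mkj,mkj->mk", d, d))        # m x k
    aff = np.column_stack([np.ones(len(points)), points]) @ model.affine
    return aff + U @ model.weights


def bending_energy(model: TpsModel) -> float:
    """Bending energy of the map: sum over x,y of w_d' K w_d (>= 0).

    Zero iff the map is affine.
    """
    K = _kernel_matrix(model.source)
    e = float(np.einsum("kd,kl,ld->", model.weights, K, model.weights))
    # quadratic form is PSD on the side-condition subspace; clip noise
    return max(e, 0.0)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """k x k bending-energy matrix of a reference shape.

    This is the upper-left k x k block of the inverse of the bordered TPS
    matrix; the bending energy of a map onto target Y is trace(Y' B Y).  It is
    symmetric PSD with a 3-dimensional null space spanned by [1, x, y].
    """
    reference = np.asarray(reference, dtype=float)
    k = reference.shape[0]
    K = _kernel_matrix(reference)
    Q = np.column_stack([np.ones(k), reference])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise DegenerateReferenceError("degenerate reference shape") from exc
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


@dataclass(frozen=True)
class BendingSpectrum:
    """Eigendecomposition of the bending-energy matrix at a reference.

    ``eigenvalues``: the k-3 strictly positive bending energies, ascending
    (large-scale warps first).  ``eigenvectors``: matching orthonormal
    k-vectors (columns), the partial-warp directions.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    reference: np.ndarray

    @property
    def n_warps(self) -> int:
        return self.eigenvalues.shape[0]


def bending_spectrum(reference: np.ndarray) -> BendingSpectrum:
    """Partial-warp spectrum of a reference configuration.

    Exactly three numerically-zero eigenvalues (the affine null space) are
    discarded; the remaining k-3 are returned ascending with orthonormal
    eigenvectors whose leading element is made positive for determinism.
    """
    reference = np.asarray(reference, dtype=float)
    k = reference.shape[0]
    B = bending_energy_matrix(reference)
    vals, vecs = np.linalg.eigh(B)
    # three smallest are the affine null space
    null_mag = np.abs(vals[:3]).max()
    pos_vals, pos_vecs = vals[3:], vecs[:, 3:]
    if pos_vals.min() <= 10 * max(null_mag, 1e-12):
        raise DegenerateReferenceError(
            "bending spectrum ill-separated: reference nearly degenerate"
        )
    # deterministic sign: largest-|.| element positive
    flip = np.sign(pos_vecs[np.abs(pos_vecs).argmax(axis=0),
                            np.arange(k - 3)])
    return BendingSpectrum(eigenvalues=pos_vals.copy(),
                           eigenvectors=pos_vecs * flip,
                           reference=reference)


def partial_warp_scores(shapes: np.ndarray, spectrum: BendingSpectrum) -> np.ndarray:
    """Project shapes onto the partial-warp basis of ``spectrum``.

    Parameters
    ----------
    shapes : (n, k, 2) aligned coordinates in the same space as the
        spectrum's reference (typically GPA-aligned shapes with the reference
        being their consensus).

    Returns
    -------
    (n, k-3, 2) array: per specimen, per warp, the x- and y-projection of the
    residual from the reference.  The affine component (the eigenvectors'
    null-space complement) carries no score; residuals minus that component
    are exactly recoverable from the scores.
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim == 2:
        shapes = shapes[None]
    if shapes.shape[1] != spectrum.reference.shape[0]:
        raise ValueError("shape/landmark count does not match spectrum reference")
    resid = shapes - spectrum.reference[None]
    # scores[n, j, d] = e_j . resid[n, :, d]
    return np.einsum("kj,nkd->njd", spectrum.eigenvectors, resid)


def jacobian_logdet_field(model: TpsModel, points: np.ndarray) -> np.ndarray:
    """log |J| of the TPS map at each evaluation point.

    The 2 x 2 Jacobian is analytic: the affine linear part plus kernel
    gradient terms dU/dx = 2 (x - xi) (1 + log r^2), with the r -> 0 limit
    set to 0.  log det J < 0 means local area reduction relative to the
    source, > 0 enlargement.  Points where det J <= 0 (a folded map) yield
    NaN and a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = points[:, None, :] - model.source[None, :, :]           # m x k x 2
    r2 = np.einsum("mkj,mkj->mk", d, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (1.0 + np.log(r2))
    g = np.where(r2 > 0.0, g, 0.0)                              # m x k
    grad = d * g[..., None]                                     # dU/d(x,y)
    # J[m, a, b] = d f_a / d p_b
    A = model.affine[1:, :]                                     # 2 x 2, rows px,py
    J = A.T[None] + np.einsum("ka,mkb->mab", model.weights, grad)
    det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    out = np.full(len(points), np.nan)
    ok = det > 0
    out[ok] = np.log(det[ok])
    if not np.all(ok):
        warnings.warn(
            f"TPS map folds at {np.count_nonzero(~ok)} evaluation point(s); "
            "log-det recorded as NaN", RuntimeWarning, stacklevel=2)
    return out


def make_grid(reference: np.ndarray, nx: int = 24, ny: int = 24,
              pad: float = 0.05) -> np.ndarray:
    """Regular evaluation grid over the reference bounding box, expanded by
    ``pad`` on each side.  Returns (nx*ny, 2) points."""
    reference = np.asarray(reference, dtype=float)
    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    span = hi - lo
    lo = lo - pad * span
    hi = hi + pad * span
    xs = np.linspace(lo[0], hi[0], nx)
    ys = np.linspace(lo[1], hi[1], ny)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])
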