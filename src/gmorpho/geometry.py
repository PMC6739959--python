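"""Procrustes superimposition, semilandmark sliding and digitization error.

Generalized Procrustes analysis (GPA) removes translation, scale and rotation
from a sample of landmark configurations, leaving shape coordinates around a
unit-centroid-size consensus.  Semilandmarks — outline points without point
homology — may additionally slide along their local tangent direction under
either the minimum bending-energy (BEN) or the minimum Procrustes-distance
(PRD) criterion before the final superimposition.

Conventions: full-Procrustes fitting (optimal scaling inside the per-shape
alignment step) with the consensus rescaled to unit centroid size each
iteration, reflections disallowed by default, tangents taken as the chord
between a slider's neighbours and recomputed on each sliding pass, endpoints
never slide.  The aligned sample is rotated to a canonical orientation
(principal axes of the consensus) so output does not depend on input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tps import bending_energy_matrix

__all__ = [
    "LandmarkConfiguration",
    "SliderTable",
    "AlignedSample",
    "MeasurementErrorResult",
    "centroid_size",
    "align_optimal",
    "gpa",
    "slide_semilandmarks",
    "procrustes_distance",
    "measurement_error",
    "species_means",
]


class DegenerateConfigurationError(ValueError):
    pass


class ShapeMismatchError(ValueError):
    pass


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration.

    Point order is the homology order and is never permuted by any operation
    in this package.
    """

    specimen_id: str
    points: np.ndarray                       # k x 2
    scale_factor: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a k x 2 array")
        if self.points.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")
        if self.scale_factor is not None and self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SliderTable:
    """Semilandmark slider definitions: rows of (before, slider, after)
    0-based indices into the template point order."""

    rows: np.ndarray                         # m x 3 int

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=int)
        if rows.size == 0:
            rows = rows.reshape(0, 3)
        if rows.ndim != 2 or rows.shape[1] != 3:
            raise ValueError("slider table must be m x 3 (before, slider, after)")
        for b, s, a in rows:
            if len({b, s, a}) != 3:
                raise ValueError(f"slider row ({b},{s},{a}) indices not distinct")
        sl = rows[:, 1]
        if len(np.unique(sl)) != len(sl):
            raise ValueError("a slider index appears more than once")
        object.__setattr__(self, "rows", rows)

    def validate(self, k: int) -> None:
        if self.rows.size and (self.rows.min() < 0 or self.rows.max() >= k):
            raise ValueError(f"slider indices out of range for k={k}")

    @property
    def sliders(self) -> np.ndarray:
        return self.rows[:, 1]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class AlignedSample:
    """GPA result: aligned shapes, original centroid sizes, consensus."""

    shapes: np.ndarray                       # n x k x 2
    centroid_sizes: np.ndarray               # n
    consensus: np.ndarray                    # k x 2
    sliding_method: str = "none"
    specimen_ids: Optional[list] = None
    converged: bool = True
    n_iterations: int = 0

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def as_matrix(self) -> np.ndarray:
        """Shapes flattened to n x 2k (x1, y1, ..., xk, yk)."""
        return self.shapes.reshape(self.n, -1)


def _points_of(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared distances of the landmarks from
    their centroid — the size variable of geometric morphometrics."""
    pts = _points_of(config)
    c = pts - pts.mean(axis=0)
    cs = float(np.sqrt((c ** 2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide: size undefined")
    return cs


def _center_scale(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    return c / np.sqrt((c ** 2).sum())


def _optimal_rotation(source: np.ndarray, target: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    """Orthogonal matrix R minimising |source @ R - target|, det forced to +1
    unless reflections are allowed."""
    U, s, Vt = np.linalg.svd(source.T @ target)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def align_optimal(source, target, allow_reflection: bool = False):
    """Ordinary Procrustes alignment of ``source`` onto ``target``.

    Both shapes are centred and scaled to unit centroid size; the optimal
    rotation comes from the SVD of their cross-product.  Returns the aligned
    source and the residual Procrustes distance (root summed squared
    coordinate differences).
    """
    s = _points_of(source)
    t = _points_of(target)
    if s.shape != t.shape:
        raise ShapeMismatchError(f"landmark counts differ: {s.shape} vs {t.shape}")
    s = _center_scale(s)
    t = _center_scale(t)
    R = _optimal_rotation(s, t, allow_reflection)
    aligned = s @ R
    d = float(np.sqrt(((aligned - t) ** 2).sum()))
    return aligned, d


def procrustes_distance(a, b, allow_reflection: bool = False) -> float:
    return align_optimal(a, b, allow_reflection)[1]


def _canonical_orientation(shapes: np.ndarray, consensus: np.ndarray):
    """Rotate the whole aligned sample so the consensus lies along its
    principal axes, sign-fixed by the first landmark.  Makes GPA output
    independent of input order and of arbitrary rotations of the inputs."""
    cov = consensus.T @ consensus
    vals, vecs = np.linalg.eigh(cov)
    R = vecs[:, ::-1].copy()                         # major axis first
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1
    c = consensus @ R
    # the remaining ambiguity is a 180-degree rotation (-I has det +1 in 2D);
    # fix it by the sign of the first landmark's larger coordinate
    j = int(np.argmax(np.abs(c[0])))
    if c[0, j] < 0:
        R = -R
    return shapes @ R, consensus @ R


def gpa(configs: Sequence, sliders: Optional[SliderTable] = None,
        method: str = "none", tol: float = 1e-10, max_iter: int = 100,
        sliding_passes: int = 3, allow_reflection: bool = False) -> AlignedSample:
    """Generalized Procrustes analysis, optionally with semilandmark sliding.

    Iteratively aligns every configuration to a provisional consensus (full
    Procrustes fit: rotation plus optimal scaling), re-estimates the consensus
    and rescales it to unit centroid size, until the consensus changes by less
    than ``tol`` (RMS) or ``max_iter`` iterations.  With ``sliders`` and
    ``method`` in {"BEN", "PRD"}, a sliding pass is interleaved after
    convergence of each superimposition round, at most ``sliding_passes``
    times.  Centroid sizes are recorded from the original configurations.
    """
    if method not in ("none", "BEN", "PRD"):
        raise ValueError(f"unknown sliding method {method!r}")
    if method != "none" and sliders is None:
        raise ValueError("sliding requested but no slider table given")
    n = len(configs)
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    pts = [_points_of(c) for c in configs]
    k = pts[0].shape[0]
    for p in pts:
        if p.shape[0] != k:
            raise ShapeMismatchError("configurations differ in landmark count")
    if sliders is not None:
        sliders.validate(k)
    ids = [c.specimen_id if isinstance(c, LandmarkConfiguration) else str(i)
           for i, c in enumerate(configs)]
    cs = np.array([centroid_size(p) for p in pts])

    X = np.stack([_center_scale(p) for p in pts])     # n x k x 2
    consensus = _center_scale(X.mean(axis=0)) if _nonzero(X.mean(axis=0)) \
        else X[0].copy()

    converged = False
    total_iter = 0

    def _superimpose(X, consensus):
        nonlocal total_iter, converged
        for _ in range(max_iter):
            total_iter += 1
            for i in range(n):
                xi = _center_scale(X[i])     # re-normalize: beta is relative
                R = _optimal_rotation(xi, consensus, allow_reflection)
                rot = xi @ R
                # full-Procrustes optimal scaling towards the consensus
                beta = np.sum(rot * consensus)
                X[i] = rot * beta
            new = X.mean(axis=0)
            new = new - new.mean(axis=0)
            new = new / np.sqrt((new ** 2).sum())
            delta = np.sqrt(((new - consensus) ** 2).mean())
            consensus = new
            if delta < tol:
                converged = True
                break
        else:
            converged = False
        return X, consensus

    X, consensus = _superimpose(X, consensus)
    if method != "none" and len(sliders) > 0:
        for _ in range(sliding_passes):
            X = slide_semilandmarks(X, consensus, sliders, method)
            X, consensus = _superimpose(X, consensus)

    if not converged:
        warnings.warn("GPA did not converge within iteration cap",
                      RuntimeWarning, stacklevel=2)
    X, consensus = _canonical_orientation(X, consensus)
    return AlignedSample(shapes=X, centroid_sizes=cs, consensus=consensus,
                         sliding_method=method, specimen_ids=ids,
                         converged=converged, n_iterations=total_iter)


def _nonzero(a: np.ndarray) -> bool:
    return float((a ** 2).sum()) > 1e-30


def slide_semilandmarks(shapes: np.ndarray, consensus: np.ndarray,
                        sliders: SliderTable, method: str) -> np.ndarray:
    """One sliding pass under the BEN or PRD criterion.

    Each semilandmark moves only along the unit chord direction from its
    ``before`` to its ``after`` neighbour at the current shape.  Displacement
    magnitudes minimise, per specimen, either the TPS bending energy of the
    consensus-to-specimen map (BEN; generalized-least-squares solution
    restricted to the tangent directions) or the summed squared distance to
    the consensus (PRD; orthogonal projection of the consensus residual onto
    the tangent).  Callers should re-superimpose afterwards (``gpa`` does).
    """
    if method not in ("BEN", "PRD"):
        raise ValueError(f"unknown sliding method {method!r}")
    shapes = np.array(shapes, dtype=float)
    single = shapes.ndim == 2
    if single:
        shapes = shapes[None]
    sliders.validate(shapes.shape[1])
    rows = sliders.rows
    if rows.size == 0:
        return shapes[0] if single else shapes

    B = bending_energy_matrix(consensus) if method == "BEN" else None

    for i in range(shapes.shape[0]):
        Y = shapes[i]
        keep, tangents = [], []
        for b, s, a in rows:
            t = Y[a] - Y[b]
            nrm = np.linalg.norm(t)
            if nrm < 1e-12:
                warnings.warn(f"zero-length tangent at slider {s}; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            keep.append(s)
            tangents.append(t / nrm)
        if not keep:
            continue
        idx = np.array(keep)
        T = np.array(tangents)                         # m x 2
        m = len(idx)
        if method == "PRD":
            # orthogonal projection of the consensus residual on the tangent
            disp = np.einsum("mj,mj->m", consensus[idx] - Y[idx], T)
        else:
            # minimise sum_d (y_d + U_d t)' B (y_d + U_d t) over t
            Ux = np.zeros((Y.shape[0], m))
            Uy = np.zeros((Y.shape[0], m))
            Ux[idx, np.arange(m)] = T[:, 0]
            Uy[idx, np.arange(m)] = T[:, 1]
            A = Ux.T @ B @ Ux + Uy.T @ B @ Uy
            rhs = -(Ux.T @ B @ Y[:, 0] + Uy.T @ B @ Y[:, 1])
            disp = np.linalg.lstsq(A, rhs, rcond=None)[0]
        Y[idx] += disp[:, None] * T
    return shapes[0] if single else shapes


@dataclass(frozen=True)
class MeasurementErrorResult:
    percent: float
    within_specimen_mean: float
    among_specimen_mean: float
    n_specimens: int


def measurement_error(replicates: Sequence[Sequence]) -> MeasurementErrorResult:
    """Digitization error from three replicate digitizations.

    All replicas of all specimens are jointly superimposed by GPA; the error
    is the mean (over specimens) of the mean pairwise Procrustes distance
    among each specimen's three replicas, expressed as a percentage of the
    mean pairwise distance among the distinct specimens' consensus (replica
    mean) forms — both measured in the same aligned space.
    """
    if len(replicates) != 3:
        raise ValueError("exactly 3 replicate datasets are required")
    ids0 = [c.specimen_id for c in replicates[0]]
    for rep in replicates[1:]:
        if [c.specimen_id for c in rep] != ids0:
            raise ValueError("replicate datasets do not match by specimen_id")
    n = len(ids0)
    if n < 2:
        raise ValueError("need at least 2 specimens")
    flat = [c for rep in replicates for c in rep]
    aligned = gpa(flat)
    S = aligned.shapes.reshape(3, n, aligned.k, 2)

    within = np.empty(n)
    for j in range(n):
        trip = S[:, j]
        d = [np.linalg.norm(trip[a] - trip[b])
             for a in range(3) for b in range(a + 1, 3)]
        within[j] = np.mean(d)
    cons = S.mean(axis=0)                               # n x k x 2
    among = [np.linalg.norm(cons[a] - cons[b])
             for a in range(n) for b in range(a + 1, n)]
    among_mean = float(np.mean(among))
    if among_mean == 0.0:
        raise DegenerateConfigurationError("no among-specimen shape variation")
    within_mean = float(within.mean())
    return MeasurementErrorResult(
        percent=100.0 * within_mean / among_mean,
        within_specimen_mean=within_mean,
        among_specimen_mean=among_mean,
        n_specimens=n,
    )


def species_means(sample: AlignedSample, species: Sequence[str]):
    """Per-species means of aligned coordinates and of centroid size.

    Run after GPA of the specimens, as a separate pipeline stage.  Returns
    (species_names, mean_shapes (s x k x 2), mean_cs (s,)).
    """
    species = np.asarray(species)
    if len(species) != sample.n:
        raise ValueError("one species label per specimen is required")
    names = sorted(set(species))
    shapes = np.empty((len(names), sample.k, 2))
    cs = np.empty(len(names))
    for i, name in enumerate(names):
        mask = species == name
        shapes[i] = sample.shapes[mask].mean(axis=0)
        cs[i] = sample.centroid_sizes[mask].mean()
    return names, shapes, cs
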