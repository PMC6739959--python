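"""Morphological integration: two-block PLS, effect sizes, major-axis
trajectories, and Bookstein-style global (intrinsic) integration.

Two-block partial least squares (PLS) decomposes the cross-covariance between
two trait blocks (e.g. two skeletal structures measured on the same
specimens) by SVD; the correlation of the first paired scores (r-PLS)
measures integration strength, with significance from permutation of one
block's rows.  Integration strength is made comparable across samples through
a permutation-standardized effect size z (Fisher-stabilized), and integration
*direction* through major-axis slopes fitted in the plane of the first PLS
score pair.

Global integration regresses log partial-warp variance on log bending energy
at the consensus: slope -1 is "self-similar" (no interpretable signal at any
spatial scale), slopes below -1 indicate integration (large-scale variation
dominates), above -1 dis-integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .tps import BendingSpectrum, partial_warp_scores

__all__ = [
    "PlsResult",
    "GlobalIntegrationResult",
    "two_block_pls",
    "pls_effect_size",
    "compare_pls",
    "major_axis_slope",
    "compare_ma_slopes",
    "global_integration_slope",
    "compare_global_integration",
]


@dataclass(frozen=True)
class PlsResult:
    singular_values: np.ndarray
    left_vectors: np.ndarray                 # p1 x a
    right_vectors: np.ndarray                # p2 x a
    left_scores: np.ndarray                  # n x a
    right_scores: np.ndarray                 # n x a
    r_per_axis: np.ndarray
    p_perm: float
    perm_r_distribution: np.ndarray
    effect_size_z: float
    se_z: float
    nperm: int
    seed: Optional[int]

    @property
    def r_pls(self) -> float:
        return float(self.r_per_axis[0])

    @property
    def n(self) -> int:
        return self.left_scores.shape[0]


def _center(Y: np.ndarray) -> np.ndarray:
    return Y - Y.mean(axis=0)


def _first_axis_r(Y1c: np.ndarray, Y2c: np.ndarray) -> float:
    """|corr| of the first pair of PLS scores (sign-free statistic)."""
    U, _, Vt = np.linalg.svd(Y1c.T @ Y2c, full_matrices=False)
    a = Y1c @ U[:, 0]
    b = Y2c @ Vt[0]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def two_block_pls(Y1: np.ndarray, Y2: np.ndarray, nperm: int = 999,
                  seed: Optional[int] = None) -> PlsResult:
    """Two-block PLS of the cross-covariance between blocks Y1 and Y2.

    Blocks are column-centred internally; paired singular vectors of
    cov(Y1, Y2) give per-axis score pairs whose Pearson correlations are the
    integration coefficients.  The permutation test shuffles rows of Y2 and
    recomputes the first-axis correlation.  Sign convention: each left
    vector's largest-magnitude element is positive, and the first axis's
    right vector is flipped if needed so r_1 >= 0.
    """
    Y1 = np.asarray(Y1, dtype=float)
    Y2 = np.asarray(Y2, dtype=float)
    if Y1.ndim == 3:
        Y1 = Y1.reshape(len(Y1), -1)
    if Y2.ndim == 3:
        Y2 = Y2.reshape(len(Y2), -1)
    if len(Y1) != len(Y2):
        raise ValueError("blocks must have the same number of rows")
    n = len(Y1)
    if n < 3:
        raise ValueError("need at least 3 observations")
    Y1c, Y2c = _center(Y1), _center(Y2)
    if np.allclose(Y1c, 0) or np.allclose(Y2c, 0):
        raise ValueError("a block has zero variance")

    U, s, Vt = np.linalg.svd(Y1c.T @ Y2c / (n - 1), full_matrices=False)
    a = min(len(s), n - 1)
    U, s, V = U[:, :a], s[:a], Vt[:a].T
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(a)])
    U, V = U * flip, V * flip
    L, Rs = Y1c @ U, Y2c @ V
    r = np.empty(a)
    for j in range(a):
        sl, sr = L[:, j].std(), Rs[:, j].std()
        r[j] = np.corrcoef(L[:, j], Rs[:, j])[0, 1] if sl > 0 and sr > 0 else 0.0
    if r[0] < 0:
        V[:, 0] *= -1
        Rs[:, 0] *= -1
        r[0] = -r[0]

    rng = np.random.default_rng(seed)
    perm_r = np.empty(nperm)
    for b in range(nperm):
        perm_r[b] = _first_axis_r(Y1c, Y2c[rng.permutation(n)])
    p = (np.count_nonzero(perm_r >= r[0]) + 1) / (nperm + 1)
    z, se = _effect_size_from_distribution(r[0], perm_r, n)
    return PlsResult(singular_values=s, left_vectors=U, right_vectors=V,
                     left_scores=L, right_scores=Rs, r_per_axis=r,
                     p_perm=float(p), perm_r_distribution=perm_r,
                     effect_size_z=z, se_z=se, nperm=nperm, seed=seed)


def _effect_size_from_distribution(r_obs: float, perm_r: np.ndarray,
                                   n: int):
    f = np.arctanh(np.clip(perm_r, -1 + 1e-12, 1 - 1e-12))
    fo = math.atanh(min(max(r_obs, -1 + 1e-12), 1 - 1e-12))
    sd = f.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(f.mean())):
        raise ValueError("degenerate permutation distribution (sd = 0)")
    z = (fo - f.mean()) / sd
    # sampling se of z: the Fisher-stabilized correlation estimate has
    # sampling sd ~ 1/sqrt(n-3) regardless of signal strength, while z is
    # standardized by the permutation-null sd; their ratio is the se of z
    se = (1.0 / math.sqrt(max(n - 3, 1))) / sd
    return float(z), float(se)


def pls_effect_size(result: PlsResult):
    """Standardized integration effect size (z) and its standard error.

    z = (arctanh r_obs - mean arctanh r_perm) / sd arctanh r_perm; the Fisher
    stabilization makes the permutation distribution close to normal so that
    z-scores from different samples are comparable.
    """
    if result.perm_r_distribution is None or len(result.perm_r_distribution) < 99:
        raise ValueError("permutation distribution with >= 99 draws required")
    return _effect_size_from_distribution(result.r_pls,
                                          result.perm_r_distribution,
                                          result.n)


def compare_pls(a: PlsResult, b: PlsResult):
    """Two-sample z-test for a difference in integration strength.

    z_diff = (z_a - z_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.  With
    the Fisher sampling se of each z this reduces to the classical
    two-sample z-test for correlations (difference of arctanh r over
    sqrt(1/(n_a-3) + 1/(n_b-3))) whenever the two permutation nulls are
    alike.
    """
    for r in (a, b):
        if r.se_z is None or not np.isfinite(r.se_z) or r.se_z <= 0:
            raise ValueError("PLS result lacks a valid effect-size se")
    z = (a.effect_size_z - b.effect_size_z) / math.hypot(a.se_z, b.se_z)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def major_axis_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Major-axis (symmetric, orthogonal-residual) regression slope.

    slope = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy);
    equals the direction of the leading eigenvector of the 2 x 2 covariance.
    With s_xy = 0 the line is axis-aligned: 0 if x varies more, +inf if y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 and syy == 0:
        raise ValueError("no variation in either variable")
    if sxy == 0:
        return 0.0 if sxx >= syy else math.inf
    return (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)


def _line_angle(x, y) -> float:
    s = major_axis_slope(x, y)
    return math.pi / 2 if math.isinf(s) else math.atan(s)


def _angle_diff(a: float, b: float) -> float:
    """Distance between two undirected line angles, in [0, pi/2]."""
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def compare_ma_slopes(group_scores: dict, nperm: int = 999,
                      seed: Optional[int] = None):
    """Pairwise permutation comparison of major-axis slopes between groups.

    ``group_scores`` maps group name -> (x, y) score arrays.  The statistic
    is the absolute difference of line angles (arctangent of the slopes),
    which stays bounded near vertical lines; the null permutes group labels
    over the pooled specimens.  Returns (slopes, pairwise p DataFrame).
    """
    import pandas as pd

    names = sorted(group_scores)
    if len(names) < 2:
        raise ValueError("at least two groups required")
    xs = {g: np.asarray(group_scores[g][0], dtype=float) for g in names}
    ys = {g: np.asarray(group_scores[g][1], dtype=float) for g in names}
    slopes = {g: major_axis_slope(xs[g], ys[g]) for g in names}
    angles = {g: _line_angle(xs[g], ys[g]) for g in names}

    pooled_x = np.concatenate([xs[g] for g in names])
    pooled_y = np.concatenate([ys[g] for g in names])
    sizes = [len(xs[g]) for g in names]
    bounds = np.cumsum([0] + sizes)
    gpairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    obs = {p: _angle_diff(angles[p[0]], angles[p[1]]) for p in gpairs}

    rng = np.random.default_rng(seed)
    counts = {p: 0 for p in gpairs}
    for _ in range(nperm):
        perm = rng.permutation(len(pooled_x))
        ang = {}
        for i, g in enumerate(names):
            sl = perm[bounds[i]:bounds[i + 1]]
            ang[g] = _line_angle(pooled_x[sl], pooled_y[sl])
        for p in gpairs:
            if _angle_diff(ang[p[0]], ang[p[1]]) >= obs[p]:
                counts[p] += 1
    pp = pd.DataFrame(np.nan, index=names, columns=names)
    for p in gpairs:
        pp.loc[p[0], p[1]] = pp.loc[p[1], p[0]] = (counts[p] + 1) / (nperm + 1)
    return slopes, pp


@dataclass(frozen=True)
class GlobalIntegrationResult:
    slope: float
    intercept: float
    points: np.ndarray                       # (k-3, 2): (log lambda, log var)
    interpretation: str
    self_similarity_tol: float


def _warp_variances(scores: np.ndarray) -> np.ndarray:
    """Per-warp variance over specimens: var of x-scores + var of y-scores."""
    return scores.var(axis=0, ddof=1).sum(axis=-1)


def global_integration_slope(shapes, spectrum: BendingSpectrum,
                             self_similarity_tol: float = 0.05,
                             ) -> GlobalIntegrationResult:
    """Bookstein's global-integration regression.

    Per partial warp, the variance over specimens of the combined (x, y)
    scores is regressed (OLS, log-log) on the warp's bending energy.  A slope
    below -1 indicates integration, above -1 dis-integration; within
    ``self_similarity_tol`` of -1 the sample is labelled self-similar.
    Zero-variance warps are dropped (their log is undefined).
    """
    shapes = getattr(shapes, "shapes", shapes)
    scores = partial_warp_scores(np.asarray(shapes, dtype=float), spectrum)
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    v = _warp_variances(scores)
    lam = spectrum.eigenvalues
    keep = v > 0
    if not np.all(keep):
        import warnings
        warnings.warn(f"{np.count_nonzero(~keep)} zero-variance warp(s) "
                      "dropped from the regression", RuntimeWarning,
                      stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable partial warps")
    x = np.log(lam[keep])
    y = np.log(v[keep])
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope + 1.0) <= self_similarity_tol:
        interp = "self-similar"
    elif slope < -1.0:
        interp = "integrated"
    else:
        interp = "dis-integrated"
    return GlobalIntegrationResult(slope=float(slope),
                                   intercept=float(intercept),
                                   points=np.column_stack([x, y]),
                                   interpretation=interp,
                                   self_similarity_tol=self_similarity_tol)


def compare_global_integration(shapes_a, shapes_b, spectrum: BendingSpectrum,
                               nperm: int = 999, seed: Optional[int] = None):
    """Permutation comparison of global-integration slopes of two groups.

    Both groups must be aligned to the same reference (the spectrum's).  The
    statistic is |slope_a - slope_b|; the null permutes specimens between the
    groups, recomputing both slopes each time.  Returns (slope_a, slope_b, p).
    """
    A = np.asarray(getattr(shapes_a, "shapes", shapes_a), dtype=float)
    B = np.asarray(getattr(shapes_b, "shapes", shapes_b), dtype=float)
    sa = partial_warp_scores(A, spectrum)
    sb = partial_warp_scores(B, spectrum)
    lam = spectrum.eigenvalues
    loglam = np.log(lam)

    def slope_of(scores):
        v = _warp_variances(scores)
        keep = v > 0
        return np.polyfit(loglam[keep], np.log(v[keep]), 1)[0]

    obs_a, obs_b = slope_of(sa), slope_of(sb)
    obs = abs(obs_a - obs_b)
    pooled = np.concatenate([sa, sb])
    na = len(sa)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nperm):
        perm = rng.permutation(len(pooled))
        d = abs(slope_of(pooled[perm[:na]]) - slope_of(pooled[perm[na:]]))
        if d >= obs:
            count += 1
    p = (count + 1) / (nperm + 1)
    return float(obs_a), float(obs_b), float(p)
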