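"""Permutation-based multivariate linear models on shape data (RRPP).

Shape responses are high-dimensional and non-normal, so classical parametric
MANOVA is unusable; instead, sums of squares are computed geometrically from
distances between fitted values and inference uses residual randomization in
a permutation procedure (RRPP): for each model term, residuals of the reduced
model are permuted, the statistic is recomputed, and

    p = (number of permuted F >= observed + 1) / (nperm + 1).

Sums of squares are sequential (type I), matching the usual morphometric
convention, with the same set of permutations reused across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "DisparityResult",
    "Term",
    "rrpp_model",
    "procrustes_anova",
    "evolutionary_allometry",
    "size_correct",
    "morphological_disparity",
]


class RankDeficientDesignError(ValueError):
    pass


@dataclass(frozen=True)
class TermResult:
    name: str
    df: int
    ss: float
    ms: float
    r_squared: float
    f: float
    z: float
    p_perm: float


@dataclass(frozen=True)
class AnovaResult:
    terms: tuple
    residual_df: int
    residual_ss: float
    total_ss: float
    nperm: int
    seed: Optional[int]
    scheme: str = "RRPP"

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t.name, "df": t.df, "SS": t.ss, "MS": t.ms,
                 "Rsq": t.r_squared, "F": t.f, "Z": t.z, "p": t.p_perm}
                for t in self.terms]
        rows.append({"term": "residual", "df": self.residual_df,
                     "SS": self.residual_ss, "MS":
                     self.residual_ss / max(self.residual_df, 1),
                     "Rsq": np.nan, "F": np.nan, "Z": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Term:
    """One model term: a factor (string labels), a covariate (numeric
    vector), or an interaction (tuple of previously named terms)."""

    name: str
    values: object


def _factor_matrix(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(set(map(str, labels)))
    if len(levels) < 2:
        raise ValueError("a factor needs at least 2 levels")
    lab = np.asarray([str(x) for x in labels])
    return np.column_stack([(lab == lv).astype(float) for lv in levels[1:]])


def _term_columns(term: Term, built: dict, n: int) -> np.ndarray:
    v = term.values
    if isinstance(v, tuple) and all(isinstance(x, str) for x in v):
        mats = [built[name] for name in v]
        cols = mats[0]
        for m in mats[1:]:
            cols = np.einsum("ni,nj->nij", cols, m).reshape(n, -1)
        return cols
    v = np.asarray(v)
    if v.dtype.kind in "OUS":
        return _factor_matrix(v)
    v = v.astype(float)
    if v.ndim == 1:
        v = v[:, None]
    return v - v.mean(axis=0)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(X) via SVD, and its rank."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


def _rrpp_nested(Y: np.ndarray, designs: Sequence[np.ndarray],
                 term_names: Sequence[str], nperm: int = 999,
                 seed: Optional[int] = None) -> AnovaResult:
    """RRPP over an explicit nested sequence of design matrices.

    ``designs[0]`` is the null (usually the intercept); each subsequent matrix
    adds one term's columns.  Exposed to sibling modules that must supply
    transformed designs (e.g. phylogenetic GLS).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    hats, ranks = [], []
    for X in designs:
        H, r = _hat(X)
        if ranks and r <= ranks[-1]:
            raise RankDeficientDesignError(
                f"term {term_names[len(ranks) - 1]!r} adds no rank "
                "(aliased with earlier terms)")
        hats.append(H)
        ranks.append(r)
    nterms = len(designs) - 1
    H_full = hats[-1]
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    E_full = Y - H_full @ Y
    ss_resid = float(np.einsum("ij,ij->", E_full, E_full))
    Yc = Y - Y.mean(axis=0)
    ss_total = float(np.einsum("ij,ij->", Yc, Yc))

    diffs = [hats[i + 1] - hats[i] for i in range(nterms)]
    dfs = [ranks[i + 1] - ranks[i] for i in range(nterms)]

    def term_stats(Ym, i):
        D = diffs[i] @ Ym
        ss = np.einsum("ij,ij->", D, D)
        R = Ym - hats[-1] @ Ym
        sse = np.einsum("ij,ij->", R, R)
        f = (ss / dfs[i]) / (sse / df_resid) if sse > 0 else np.inf
        return ss, f

    obs = [term_stats(Y, i) for i in range(nterms)]

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(nperm)])
    f_perm = np.empty((nterms, nperm))
    for i in range(nterms):
        fitted = hats[i] @ Y
        resid = Y - fitted
        for b in range(nperm):
            Ym = fitted + resid[perms[b]]
            f_perm[i, b] = term_stats(Ym, i)[1]

    results = []
    for i in range(nterms):
        ss, f = obs[i]
        p = (np.count_nonzero(f_perm[i] >= f) + 1) / (nperm + 1)
        with np.errstate(divide="ignore"):
            logs = np.log(np.concatenate([[f], f_perm[i]]))
        logs = logs[np.isfinite(logs)]
        sd = logs[1:].std(ddof=1) if len(logs) > 2 else 0.0
        z = (np.log(f) - np.log(f_perm[i]).mean()) / sd \
            if sd > 0 and np.isfinite(np.log(f)) else np.nan
        results.append(TermResult(
            name=term_names[i], df=dfs[i], ss=float(ss),
            ms=float(ss / dfs[i]), r_squared=float(ss / ss_total),
            f=float(f), z=float(z), p_perm=float(p)))
    return AnovaResult(terms=tuple(results), residual_df=df_resid,
                       residual_ss=ss_resid, total_ss=ss_total,
                       nperm=nperm, seed=seed)


def rrpp_model(Y: np.ndarray, terms: Sequence[Term], nperm: int = 999,
               seed: Optional[int] = None) -> AnovaResult:
    """Sequential (type I) multivariate linear model with RRPP inference.

    ``terms`` are added in order on top of an intercept; interactions refer
    to earlier terms by name, e.g.::

        rrpp_model(Y, [Term("size", cs), Term("group", labels),
                       Term("size:group", ("size", "group"))])
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(len(Y), -1)
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    n = len(Y)
    built: dict = {}
    designs = [np.ones((n, 1))]
    names = []
    for t in terms:
        cols = _term_columns(t, built, n)
        if np.ptp(cols, axis=0).max() == 0:
            raise ValueError(f"term {t.name!r} is constant")
        built[t.name] = cols
        designs.append(np.hstack([designs[-1], cols]))
        names.append(t.name)
    return _rrpp_nested(Y, designs, names, nperm=nperm, seed=seed)


def procrustes_anova(shapes: np.ndarray, groups: Sequence, nperm: int = 999,
                     seed: Optional[int] = None) -> AnovaResult:
    """Procrustes ANOVA: do aligned shapes differ between groups?

    A single-factor RRPP model on the flattened Procrustes coordinates.
    """
    groups = np.asarray([str(g) for g in groups])
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members "
                         "(no residual df otherwise)")
    return rrpp_model(shapes, [Term("groups", groups)], nperm=nperm, seed=seed)


def evolutionary_allometry(shapes: np.ndarray, cs: np.ndarray,
                           groups: Sequence, nperm: int = 999,
                           seed: Optional[int] = None,
                           log_size: bool = False) -> AnovaResult:
    """Shape ~ CS + group + CS x group.

    The interaction term is the homogeneity-of-slopes test: a significant
    CS x group term means the groups' allometric trajectories differ in
    direction.  ``log_size`` switches the covariate to log(CS).
    """
    cs = np.asarray(cs, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    if np.ptp(cs) == 0:
        raise ValueError("centroid size is constant")
    x = np.log(cs) if log_size else cs
    return rrpp_model(
        shapes,
        [Term("size", x), Term("groups", np.asarray(groups)),
         Term("size:groups", ("size", "groups"))],
        nperm=nperm, seed=seed)


def size_correct(shapes: np.ndarray, cs: np.ndarray) -> np.ndarray:
    """Size-free shape coordinates.

    Residuals of the multivariate regression of shapes on centroid size, with
    the mean shape added back so the output stays shape-like.  The output is
    exactly uncorrelated with CS.
    """
    shapes = np.asarray(shapes, dtype=float)
    orig_shape = shapes.shape
    Y = shapes.reshape(len(shapes), -1)
    cs = np.asarray(cs, dtype=float)
    if np.ptp(cs) == 0:
        raise ValueError("centroid size is constant")
    x = cs - cs.mean()
    Yc = Y - Y.mean(axis=0)
    beta = (x @ Yc) / (x @ x)
    resid = Yc - np.outer(x, beta)
    return (resid + Y.mean(axis=0)).reshape(orig_shape)


@dataclass(frozen=True)
class DisparityResult:
    groups: tuple
    group_variances: np.ndarray
    pairwise_abs_diffs: pd.DataFrame
    pairwise_p_perm: pd.DataFrame
    nperm: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": list(self.groups),
                             "procrustes_variance": self.group_variances})


def morphological_disparity(shapes: np.ndarray, groups: Sequence,
                            covariate: Optional[np.ndarray] = None,
                            nperm: int = 999, seed: Optional[int] = None,
                            permute_labels: bool = False) -> DisparityResult:
    """Procrustes variance per group with pairwise permutation tests.

    Procrustes variance (PV) of a group is the trace of its covariance matrix
    with divisor n_g — equivalently the mean squared Procrustes deviation
    from the group mean.  The pairwise statistic is |PV_A - PV_B|; its null
    is built by permuting residuals of the group-mean model (with the
    covariate partialled out first when given) across specimens.  With
    ``permute_labels`` the group labels themselves are permuted instead.
    """
    shapes = np.asarray(shapes, dtype=float)
    Y = shapes.reshape(len(shapes), -1)
    groups = np.asarray([str(g) for g in groups])
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("at least 2 groups required")
    masks = {g: groups == g for g in names}
    for g, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    X = [np.ones((len(Y), 1))]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)[:, None]
        X.append(cov - cov.mean(axis=0))
    X.append(_factor_matrix(groups))
    H, _ = _hat(np.hstack(X))
    E = Y - H @ Y

    def pvs(E):
        return np.array([np.einsum("ij,ij->", E[masks[g]], E[masks[g]])
                         / masks[g].sum() for g in names])

    obs_pv = pvs(E)
    gpairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    obs_diff = {p: abs(obs_pv[names.index(p[0])] - obs_pv[names.index(p[1])])
                for p in gpairs}

    rng = np.random.default_rng(seed)
    sq = np.einsum("ij,ij->i", E, E)          # squared residual norms
    counts = {p: 0 for p in gpairs}
    for _ in range(nperm):
        if permute_labels:
            gperm = groups[rng.permutation(len(Y))]
            pm = {g: gperm == g for g in names}
            pv = np.array([sq[pm[g]].mean() for g in names])
        else:
            sqp = sq[rng.permutation(len(Y))]
            pv = np.array([sqp[masks[g]].mean() for g in names])
        for p in gpairs:
            d = abs(pv[names.index(p[0])] - pv[names.index(p[1])])
            if d >= obs_diff[p]:
                counts[p] += 1

    dd = pd.DataFrame(np.nan, index=names, columns=names)
    pp = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b) in gpairs:
        dd.loc[a, b] = dd.loc[b, a] = obs_diff[(a, b)]
        pp.loc[a, b] = pp.loc[b, a] = (counts[(a, b)] + 1) / (nperm + 1)
    return DisparityResult(groups=tuple(names), group_variances=obs_pv,
                           pairwise_abs_diffs=dd, pairwise_p_perm=pp,
                           nperm=nperm, seed=seed)
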