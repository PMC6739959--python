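"""Between-group principal component analysis (bgPCA).

bgPCA builds a morphospace from the principal components of the *group
means* (typically species means) and projects every specimen onto those
axes.  Unlike ordinary PCA it remains well behaved when each group has far
fewer observations than shape variables, the usual situation in geometric
morphometrics; at most g - 1 axes exist for g groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BgPcaResult", "bg_pca"]


@dataclass(frozen=True)
class BgPcaResult:
    axes: np.ndarray                         # p x a orthonormal loadings
    scores: np.ndarray                       # n x a specimen scores
    group_means_scores: np.ndarray           # g x a
    group_names: tuple
    percent_variance: np.ndarray             # of group-mean variance, sums to 100
    percent_total_variance: np.ndarray       # of total specimen variance
    center: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def scree(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis": np.arange(1, self.n_axes + 1),
            "pct_group_mean_variance": self.percent_variance,
            "pct_total_variance": self.percent_total_variance,
        })


def bg_pca(X: np.ndarray, groups: Sequence) -> BgPcaResult:
    """Between-group PCA of ``X`` (n x p shape variables) with group labels.

    Axes are the eigenvectors of the covariance of the group means (groups
    weighted equally); specimens are projected after centring on the grand
    mean of the group means.  Axis signs are standardized so each axis's
    largest-magnitude loading is positive.

    Per-axis variance shares are reported both relative to the group-mean
    covariance total (the bgPCA-native convention) and relative to total
    specimen variance in the retained subspace, since published percentages
    use either convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    groups = np.asarray([str(g) for g in groups])
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("bgPCA needs at least 2 groups")
    for g in names:
        if not np.any(groups == g):
            raise ValueError(f"empty group {g!r}")
    means = np.stack([X[groups == g].mean(axis=0) for g in names])
    center = means.mean(axis=0)
    M = means - center

    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    tol = s[0] * max(M.shape) * np.finfo(float).eps if s.size else 0.0
    a = min(int(np.sum(s > tol)), len(names) - 1)
    axes = Vt[:a].T                           # p x a
    flip = np.sign(axes[np.abs(axes).argmax(axis=0), np.arange(a)])
    axes = axes * flip

    eig = s[:a] ** 2 / max(len(names) - 1, 1)
    pct = 100.0 * eig / eig.sum()
    scores = (X - center) @ axes
    total_var = ((X - X.mean(axis=0)) ** 2).sum() / max(len(X) - 1, 1)
    axis_var = scores.var(axis=0, ddof=1)
    pct_total = 100.0 * axis_var / total_var
    return BgPcaResult(axes=axes, scores=scores,
                       group_means_scores=M @ axes,
                       group_names=tuple(names),
                       percent_variance=pct,
                       percent_total_variance=pct_total,
                       center=center)
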