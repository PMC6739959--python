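"""Phylogenetic comparative layer under a Brownian-motion (BM) model.

Species cannot be treated as independent observations: under BM the expected
covariance of a trait between two species equals the shared path length from
the root to their most recent common ancestor.  This module derives that
covariance matrix C from a time-calibrated tree and builds on it

* ``kmult`` — multivariate phylogenetic signal (the multivariate
  generalization of Blomberg's K; K = 1 is the BM expectation),
* ``phylo_procrustes_anova`` — Procrustes ANOVA after a generalized
  least-squares (GLS) transform by C^(-1/2),
* ``phylo_pls`` — two-block partial least squares on GLS-transformed blocks
  (phylogenetic integration).

C^(-1/2) is taken from the symmetric eigendecomposition, not a Cholesky
factor, so results do not depend on species ordering conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .integration import PlsResult, two_block_pls
from .linear_models import AnovaResult, _factor_matrix, _rrpp_nested

__all__ = [
    "Phylogeny",
    "KmultResult",
    "bm_covariance",
    "kmult",
    "phylo_procrustes_anova",
    "phylo_pls",
]


class Phylogeny:
    """Rooted, branch-length-bearing tree over species names.

    Thin wrapper around a :class:`dendropy.Tree` adding the Brownian
    covariance matrix and validation.  Tip order is the order of
    ``taxon_names`` unless a ``species_order`` is passed to
    :meth:`covariance`.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tip names: {dups}")
        self.taxon_names = names
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in tree")
        zero_terminals = [lf.taxon.label for lf in tree.leaf_node_iter()
                          if (lf.edge.length or 0.0) == 0.0]
        self.zero_length_terminals = zero_terminals
        if zero_terminals:
            warnings.warn(
                f"{len(zero_terminals)} zero-length terminal branch(es): "
                f"{zero_terminals[:5]}", RuntimeWarning, stacklevel=2)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"Newick parse failed: {exc}") from exc
        return cls(tree)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def n_tips(self) -> int:
        return len(self.taxon_names)

    def depth(self) -> float:
        return max(self.covariance().diagonal())

    def covariance(self, species_order: Optional[Sequence[str]] = None) -> np.ndarray:
        """Brownian covariance: C[i, j] = depth of MRCA(i, j); diagonal =
        root-to-tip path lengths."""
        return bm_covariance(self, species_order)


def bm_covariance(tree: Phylogeny,
                  species_order: Optional[Sequence[str]] = None) -> np.ndarray:
    """N x N Brownian-motion covariance matrix of the tips of ``tree``.

    Raises if any requested species is missing from the tree.
    """
    if species_order is None:
        species_order = tree.taxon_names
    missing = [s for s in species_order if s not in tree.taxon_names]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    t = tree.tree
    # node depths from the root
    depth = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    idx = {name: i for i, name in enumerate(species_order)}
    N = len(species_order)
    C = np.zeros((N, N))
    for node in t.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            if name in idx:
                C[idx[name], idx[name]] = depth[node]
            node.tip_set = frozenset([name]) if name in idx else frozenset()
        else:
            children = node.child_nodes()
            sets = [ch.tip_set for ch in children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for na in sets[a]:
                        for nb in sets[b]:
                            C[idx[na], idx[nb]] = depth[node]
                            C[idx[nb], idx[na]] = depth[node]
            node.tip_set = frozenset().union(*sets)
    return C


def _regularized(C: np.ndarray, tree_depth: float) -> np.ndarray:
    """Perturb a singular C (zero-length branches) just enough to invert."""
    eps = 1e-8 * tree_depth
    vals = np.linalg.eigvalsh(C)
    if vals.min() < eps:
        warnings.warn("near-singular phylogenetic covariance; adding "
                      f"{eps:.2e} to the diagonal", RuntimeWarning, stacklevel=3)
        C = C + eps * np.eye(len(C))
    return C


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _phylo_mean(Y: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    one = np.ones(len(Y))
    w = Cinv @ one
    return (w @ Y) / (one @ w)


@dataclass(frozen=True)
class KmultResult:
    k_mult: float
    p_perm: float
    nperm: int
    seed: Optional[int]
    perm_distribution: np.ndarray


def kmult(Y: np.ndarray, tree: Phylogeny, species: Sequence[str],
          nperm: int = 999, seed: Optional[int] = None) -> KmultResult:
    """Multivariate phylogenetic signal K_mult of species means ``Y``.

    K_mult compares observed trait similarity among relatives with the BM
    expectation::

        K = [ tr(D'D) / tr(D' C^-1 D) ] / [ (tr C - N / (1'C^-1 1)) / (N-1) ]

    with D = Y - 1 a_hat the deviations from the phylogenetic (GLS) grand
    mean.  K = 1 matches BM exactly on a star tree and in expectation on any
    tree; K > 1 means more similarity among relatives than BM predicts.
    Significance: species rows are shuffled across tips and K recomputed.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    N = len(Y)
    if N < 4:
        raise ValueError("K_mult needs at least 4 species")
    C = tree.covariance(list(species))
    C = _regularized(C, float(C.diagonal().max()))
    Cinv = np.linalg.inv(C)
    denom_scale = (np.trace(C) - N / np.ones(N).dot(Cinv).dot(np.ones(N))) / (N - 1)

    def stat(Yp):
        D = Yp - _phylo_mean(Yp, Cinv)
        num = np.einsum("ij,ij->", D, D)
        den = np.einsum("ij,ik,kj->", D, Cinv, D)
        if den <= 0:
            raise ValueError("undefined K_mult: no variation among species")
        return (num / den) / denom_scale

    obs = stat(Y)
    rng = np.random.default_rng(seed)
    perm = np.empty(nperm)
    for i in range(nperm):
        perm[i] = stat(Y[rng.permutation(N)])
    p = (np.count_nonzero(perm >= obs) + 1) / (nperm + 1)
    return KmultResult(k_mult=float(obs), p_perm=float(p), nperm=nperm,
                       seed=seed, perm_distribution=perm)


def _gls_transform(Y: np.ndarray, tree: Phylogeny, species: Sequence[str]):
    """Return (P, Y_tilde): P = C^(-1/2) and the GLS-centred, transformed
    data P (Y - 1 a_hat)."""
    Y = np.asarray(Y, dtype=float)
    C = tree.covariance(list(species))
    C = _regularized(C, float(C.diagonal().max()))
    Cinv = np.linalg.inv(C)
    P = _inv_sqrt(C)
    a = _phylo_mean(Y, Cinv)
    return P, P @ (Y - a)


def phylo_procrustes_anova(Y: np.ndarray, groups: Sequence, tree: Phylogeny,
                           species: Sequence[str], nperm: int = 999,
                           seed: Optional[int] = None) -> AnovaResult:
    """Procrustes ANOVA of species means by group in a phylogenetic (BM-GLS)
    framework.

    Both the response and the design are premultiplied by C^(-1/2); on a star
    tree this reduces exactly to the ordinary Procrustes ANOVA.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(len(Y), -1)
    P, Yt = _gls_transform(Y, tree, species)
    G = _factor_matrix(np.asarray(groups))
    one = np.ones((len(Y), 1))
    X0 = P @ one
    X1 = np.hstack([X0, P @ G])
    return _rrpp_nested(Yt, [X0, X1], ["groups"], nperm=nperm, seed=seed)


def phylo_pls(Y1: np.ndarray, Y2: np.ndarray, tree: Phylogeny,
              species: Sequence[str], nperm: int = 999,
              seed: Optional[int] = None,
              permute: str = "transformed") -> PlsResult:
    """Phylogenetic two-block PLS: integration between two trait blocks after
    removing BM-expected covariance due to shared ancestry.

    Both blocks are GLS-transformed by C^(-1/2) about their phylogenetic
    means, then ordinary two-block PLS runs on the transformed rows.  On a
    star tree this equals ordinary PLS to machine precision.

    ``permute`` chooses the null's permutation unit.  "transformed"
    (default) shuffles the GLS-transformed rows, which are exchangeable
    under the Brownian null and give a correctly calibrated test.  "raw"
    shuffles the species-to-tip assignment of the second block's original
    rows and re-transforms each time; this null is markedly anti-conservative
    under independent Brownian evolution and is provided for comparison
    only.

    The singular-vector shape deformations of a phylogenetic PLS are not
    directly interpretable as shapes; downstream visualization should use the
    ordinary PLS instead.
    """
    if permute not in ("raw", "transformed"):
        raise ValueError(f"unknown permutation unit {permute!r}")
    Y1 = np.asarray(Y1, dtype=float)
    Y2 = np.asarray(Y2, dtype=float)
    if Y1.ndim == 3:
        Y1 = Y1.reshape(len(Y1), -1)
    if Y2.ndim == 3:
        Y2 = Y2.reshape(len(Y2), -1)
    if len(Y1) != len(Y2):
        raise ValueError("blocks must cover the same species")
    P, Y1t = _gls_transform(Y1, tree, species)
    _, Y2t = _gls_transform(Y2, tree, species)
    if permute == "transformed":
        return two_block_pls(Y1t, Y2t, nperm=nperm, seed=seed)

    from .integration import (_center, _effect_size_from_distribution,
                              _first_axis_r)

    res = two_block_pls(Y1t, Y2t, nperm=nperm, seed=seed)
    C = tree.covariance(list(species))
    C = _regularized(C, float(C.diagonal().max()))
    Cinv = np.linalg.inv(C)
    Y1c = _center(Y1t)
    rng = np.random.default_rng(seed)
    n = len(Y2)
    perm_r = np.empty(nperm)
    for b in range(nperm):
        Yp = Y2[rng.permutation(n)]
        Ypt = P @ (Yp - _phylo_mean(Yp, Cinv))
        perm_r[b] = _first_axis_r(Y1c, _center(Ypt))
    p = (np.count_nonzero(perm_r >= res.r_pls) + 1) / (nperm + 1)
    z, se = _effect_size_from_distribution(res.r_pls, perm_r, n)
    return PlsResult(
        singular_values=res.singular_values, left_vectors=res.left_vectors,
        right_vectors=res.right_vectors, left_scores=res.left_scores,
        right_scores=res.right_scores, r_per_axis=res.r_per_axis,
        p_perm=float(p), perm_r_distribution=perm_r, effect_size_z=z,
        se_z=se, nperm=nperm, seed=seed)
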