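"""Synthetic data with the statistical structure of a two-structure,
two-lifestyle landmark study.

The generator emulates a design of 37 mole-like species in two ecological
groups (26 subterranean, 11 non-subterranean), each species carrying two
landmarked structures — a 36-point humerus-like template (22 fixed landmarks
+ 14 semilandmarks) and a 38-point mandible-like template (12 + 26) — with

* species mean shapes evolved by Brownian motion on a pure-birth tree,
  generated in the partial-warp basis of the template with per-warp variance
  proportional to ``lambda^(-c)`` (so the Bookstein global-integration slope
  is analytically ``-c``), plus a small uniform (affine) component;
* a shared latent factor with loading sqrt(rho) inducing cross-structure
  covariation (integration) of controllable strength;
* a lifestyle mean offset along a fixed deformation direction and a
  controllable within-group disparity ratio;
* per-species specimens with lognormal centroid sizes, allometric shape
  change along group-specific slope vectors, isotropic digitization noise,
  Table-1-like sample-size imbalance (2-59 per species), and optional
  triplicate digitization replicates.

All randomness flows from the config seed; identical configs give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration, SliderTable, centroid_size
from .phylo import Phylogeny
from .tps import BendingSpectrum, bending_spectrum

__all__ = [
    "GeneratorConfig",
    "StructureSample",
    "SyntheticDataset",
    "make_template",
    "simulate_tree",
    "simulate_species_shapes",
    "simulate_specimens",
    "simulate_dataset",
    "simulate_warp_sample",
    "calibrated_replicate_noise",
]

TEMPLATE_KINDS = ("humerus36", "mandible38")

# 1-based semilandmark positions, after the figure-caption curve ranges:
# humerus outline curves (teres tubercle surface 12-14, minor sulcus 16-18,
# greater sulcus 29-32, humeral head 33-36) -> 14 sliders of 36;
# mandible curves with their endpoints fixed -> 26 sliders of 38.
_HUMERUS_SLIDERS_1B = [12, 13, 14, 16, 17, 18, 29, 30, 31, 32, 33, 34, 35, 36]
_MANDIBLE_SLIDERS_1B = ([6, 7, 8] + [10, 11, 12] + [14, 15, 16]
                        + list(range(18, 24)) + list(range(25, 30))
                        + list(range(32, 38)))


def _outline(k: int, harmonics: Sequence[Tuple[int, float, float]]) -> np.ndarray:
    """Smooth star-shaped closed outline: r(theta) = 1 + sum a cos + b sin.

    Star-shaped with r > 0 everywhere, hence non-self-intersecting.
    """
    theta = 2 * np.pi * np.arange(k) / k
    r = np.ones(k)
    for order, a, b in harmonics:
        r = r + a * np.cos(order * theta) + b * np.sin(order * theta)
    if r.min() <= 0.05:
        raise ValueError("outline harmonics too strong: self-intersection risk")
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pts -= pts.mean(axis=0)
    return pts / centroid_size(pts)


def make_template(kind: str) -> Tuple[LandmarkConfiguration, SliderTable]:
    """Template configuration and slider table for a known kind.

    ``humerus36``: 36 outline points, 22 fixed + 14 semilandmarks.
    ``mandible38``: 38 outline points, 12 fixed + 26 semilandmarks.
    Sliders sit on smooth outline segments; each slider's before/after
    neighbours are the adjacent outline points (closed outline, wrapping).
    """
    if kind == "humerus36":
        k = 36
        pts = _outline(k, [(2, 0.22, 0.0), (3, 0.0, 0.10), (5, 0.04, 0.0)])
        sliders_1b = _HUMERUS_SLIDERS_1B
    elif kind == "mandible38":
        k = 38
        pts = _outline(k, [(2, 0.30, 0.05), (3, 0.08, 0.0), (4, 0.0, 0.05)])
        sliders_1b = _MANDIBLE_SLIDERS_1B
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    rows = [((s - 2) % k, s - 1, s % k) for s in sliders_1b]
    return (LandmarkConfiguration(specimen_id=kind, points=pts),
            SliderTable(rows=np.array(rows, dtype=int)))


def simulate_tree(n_tips: int, seed: Optional[int] = None) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, scaled to unit
    depth, tips labelled sp001, sp002, ... in tree order."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    # node: [split_time, left, right]; a leaf has left is None.  The process
    # starts at the root split (time 0) so tip depths are exactly 1 after
    # scaling.
    root = [0.0, [None, None, None], [None, None, None]]
    active = [root[1], root[2]]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node[0] = t
        node[1] = [None, None, None]
        node[2] = [None, None, None]
        active.extend([node[1], node[2]])
    depth = t + rng.exponential(1.0 / len(active))
    counter = [0]

    def build(node, parent_split: float) -> str:
        if node[1] is None:
            counter[0] += 1
            return f"sp{counter[0]:03d}:{(depth - parent_split) / depth:.12f}"
        s = node[0]
        return (f"({build(node[1], s)},{build(node[2], s)})"
                f":{(s - parent_split) / depth:.12f}")

    newick = f"({build(root[1], 0.0)},{build(root[2], 0.0)});"
    return Phylogeny.from_newick(newick)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the emulated design: 37 species, 26 subterranean,
    both structures, integration rho 0.85, disparity ratio 4 (non-subterranean
    more disparate), spectrum exponents 1.3 (humerus-like) and 2.0
    (mandible-like, the more integrated structure), Table-1-like specimen
    counts, digitization replicates calibrated near a 0.8% error ratio.
    """

    templates: Tuple[str, ...] = ("humerus36", "mandible38")
    n_species: int = 37
    n_subterranean: int = 26
    bm_rate: float = 0.01                    # total shape variance per unit time
    spectrum_exponent: Dict[str, float] = field(
        default_factory=lambda: {"humerus36": 1.3, "mandible38": 2.0})
    uniform_fraction: float = 0.05           # affine share of total variance
    group_mean_offset: float = 0.15
    disparity_ratio: float = 4.0             # non-subterranean / subterranean
    # scalar, or {"subterranean": r1, "non-subterranean": r2} for a
    # clade-restricted integration factor
    integration_rho: object = 0.85
    allometry_common: float = 0.03           # shape change per sd of CS
    allometry_group_delta: float = 0.0       # extra group-B slope, 45 deg away
    specimen_noise_sd: float = 0.005         # per coordinate, unit-CS scale
    replicate_noise_sd: float = 1e-4
    n_replicates: int = 0                    # 0 or 3
    # subterranean = a clade (realistic; the lifestyle groups are clades) or
    # a random tip set (exchangeable: use for calibration/null checks)
    clade_groups: bool = True
    # fraction of the non-subterranean group's variance placed on the main
    # (integration) axis; None spreads the disparity excess evenly
    nonsub_axis_share: Optional[float] = None
    balanced: bool = False
    n_per_species: int = 10                  # used when balanced
    seed: int = 0

    def __post_init__(self):
        rhos = (self.integration_rho.values()
                if isinstance(self.integration_rho, dict)
                else [self.integration_rho])
        if not all(0.0 <= r <= 1.0 for r in rhos):
            raise ValueError("integration_rho must be in [0, 1]")
        for v in (self.specimen_noise_sd, self.replicate_noise_sd,
                  self.bm_rate, self.group_mean_offset):
            if v < 0:
                raise ValueError("rates, sds and offsets must be >= 0")
        if self.disparity_ratio <= 0:
            raise ValueError("disparity_ratio must be positive")
        if self.n_replicates not in (0, 3):
            raise ValueError("replicates are triplicate or absent")
        if not 0 < self.n_subterranean < self.n_species:
            raise ValueError("both groups must be non-empty")

    def exponent(self, kind: str) -> float:
        if isinstance(self.spectrum_exponent, dict):
            return self.spectrum_exponent.get(kind, 1.0)
        return float(self.spectrum_exponent)

    def rho(self, group: str) -> float:
        if isinstance(self.integration_rho, dict):
            return float(self.integration_rho[group])
        return float(self.integration_rho)

    @classmethod
    def talpid_study(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """The configuration emulating the talpid study's design.

        Each lifestyle group carries its own correlated-BM integration
        factor (rho 0.85 subterranean, 0.7 non-subterranean, the latter
        anti-loaded in the second structure so the groups' contributions to
        whole-sample cross-covariance partly cancel), a lifestyle mean
        offset on the subterranean clade, and a 4x disparity contrast.
        """
        kw = dict(integration_rho={"subterranean": 0.85,
                                   "non-subterranean": 0.7},
                  group_mean_offset=0.15, disparity_ratio=4.0, seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class StructureSample:
    kind: str
    template: LandmarkConfiguration
    sliders: SliderTable
    spectrum: BendingSpectrum
    species_means: np.ndarray                # N x k x 2
    mean_scores: np.ndarray                  # N x (k-3) x 2 (warp scores)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    tree: Phylogeny
    species: List[str]
    groups: List[str]                        # per species
    structures: Dict[str, StructureSample]
    specimens: Dict[str, List[LandmarkConfiguration]] = field(default_factory=dict)
    specimen_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    replicates: Dict[str, List[List[LandmarkConfiguration]]] = field(default_factory=dict)

    def specimen_table(self) -> pd.DataFrame:
        return pd.concat(self.specimen_tables.values(), ignore_index=True)


def _clade_near_size(tree: Phylogeny, target: int) -> frozenset:
    """Tip labels of the clade whose size is closest to ``target`` (never the
    full tree; ties resolved towards larger clades, then tree order)."""
    best, best_key = None, None
    n_total = tree.n_tips
    for node in tree.tree.preorder_node_iter():
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        if len(tips) >= n_total or len(tips) < 2:
            continue
        key = (abs(len(tips) - target), -len(tips))
        if best_key is None or key < best_key:
            best, best_key = frozenset(tips), key
    return best


def _bm_deviates(L: np.ndarray, rng: np.random.Generator, ncols: int) -> np.ndarray:
    """N x ncols columns of unit-rate BM tip deviations on the tree
    (L = Cholesky factor of the BM covariance)."""
    return L @ rng.standard_normal((L.shape[0], ncols))


def _uniform_basis(reference: np.ndarray) -> np.ndarray:
    """Two orthonormal k*2 fields spanning the uniform (affine, non-similarity)
    shape component at the reference: shear and anisotropic scaling."""
    x, y = reference[:, 0], reference[:, 1]
    u1 = np.column_stack([y, np.zeros_like(y)]).ravel()          # x-shear
    u2 = np.column_stack([x, -y]).ravel()                        # aniso scale
    basis, _ = np.linalg.qr(np.column_stack([u1, u2]))
    return basis                                                 # 2k x 2


def simulate_species_shapes(config: GeneratorConfig, tree: Phylogeny
                            ) -> SyntheticDataset:
    """Species mean shapes per structure, evolved by BM on ``tree``.

    Scores are generated in each template's partial-warp basis with variance
    proportional to lambda^(-c); the highest-variance warp dimension of each
    structure shares a latent BM factor with loading sqrt(rho), inducing
    cross-structure covariation with score correlation rho.  Subterranean
    species receive a fixed deformation offset; non-subterranean deviations
    from their group mean are inflated to realize the disparity ratio.
    """
    rng = np.random.default_rng(config.seed)
    species = list(tree.taxon_names)
    if len(species) != config.n_species:
        raise ValueError("tree tip count does not match n_species")
    # the subterranean group is by default a clade (the one closest in size
    # to the target), like the real lifestyle clades: a clade-level mean
    # offset is then a Brownian-plausible stem innovation.  Random groups are
    # exchangeable and give calibrated naive tests.
    if config.clade_groups:
        sub_species = _clade_near_size(tree, config.n_subterranean)
    else:
        sub_species = frozenset(
            rng.permutation(species)[:config.n_subterranean])
    groups = ["subterranean" if s in sub_species else "non-subterranean"
              for s in species]
    C = tree.covariance(species)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    # cross-structure latents: one per group when rho is group-specific
    shared = _bm_deviates(L, rng, 1)[:, 0]
    shared_b = _bm_deviates(L, rng, 1)[:, 0]

    structures: Dict[str, StructureSample] = {}
    sub = np.array([g == "subterranean" for g in groups])
    drawn = {}
    for kind in config.templates:
        template, sliders = make_template(kind)
        spectrum = bending_spectrum(template.points)
        w = spectrum.n_warps
        c = config.exponent(kind)
        lam = spectrum.eigenvalues
        wvar = lam ** (-c)
        wvar = wvar / wvar.sum() * config.bm_rate * (1 - config.uniform_fraction)
        sd = np.sqrt(np.repeat(wvar / 2.0, 2))           # per (warp, coord)

        Z = _bm_deviates(L, rng, 2 * w)
        # shared factor enters the largest-variance score dimension (the
        # first: eigenvalues ascend, so lambda^-c peaks at warp 1); with
        # group-specific rho each group gets its own latent on its own axis
        if isinstance(config.integration_rho, dict):
            # group-specific latents on the same axis; the non-subterranean
            # latent loads with opposite sign in the second structure, so the
            # two groups' contributions to the whole-sample cross-covariance
            # partly cancel (within-group integration is unaffected: a PLS
            # axis pair is defined only up to a joint sign)
            second = kind == config.templates[-1] and len(config.templates) > 1
            latent = {"subterranean": (shared, 1.0),
                      "non-subterranean": (shared_b, -1.0 if second else 1.0)}
            for g in set(groups):
                rho = config.rho(g)
                u, sign = latent[g]
                m = np.array([x == g for x in groups])
                Z[m, 0] = (sign * math.sqrt(rho) * u[m]
                           + math.sqrt(1 - rho) * Z[m, 0])
        else:
            rho = config.rho("subterranean")
            Z[:, 0] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * Z[:, 0]
        ua = _bm_deviates(L, rng, 2)                     # uniform component
        drawn[kind] = (template, sliders, spectrum, sd, Z, ua)

    # disparity contrast: the groups sit on different parts of the tree, so
    # their realized within-group BM variances differ; rescale the
    # non-subterranean deviations about their group mean to hit the
    # configured ratio of realized variances exactly, per structure.  The
    # shared (integration) column is scaled by one factor common to both
    # structures so cross-structure correlation survives; the remaining
    # columns absorb the per-structure remainder.
    def _col_ssd(M, mask):
        D = M[mask] - M[mask].mean(axis=0)
        return (D ** 2).mean(axis=0)          # per-column mean sq deviation

    uvar = config.bm_rate * config.uniform_fraction / 2.0
    ratio = config.disparity_ratio
    shared_sub = shared_non = 0.0
    for _, _, _, sd, Z, ua in drawn.values():
        shared_sub += sd[0] ** 2 * _col_ssd(Z[:, [0]], sub)[0]
        shared_non += sd[0] ** 2 * _col_ssd(Z[:, [0]], ~sub)[0]
    f_shared = math.sqrt(ratio * shared_sub / shared_non)
    for kind in config.templates:
        template, sliders, spectrum, sd, Z, ua = drawn[kind]
        w = spectrum.n_warps
        W = np.hstack([Z * sd, ua * math.sqrt(uvar)])     # weighted columns
        sub_tot = _col_ssd(W, sub).sum()
        non_cols = _col_ssd(W, ~sub)
        if config.nonsub_axis_share is not None:
            share = config.nonsub_axis_share
            f_shared = math.sqrt(share * ratio * sub_tot / non_cols[0])
        rest_target = ratio * sub_tot - f_shared ** 2 * non_cols[0]
        rest = non_cols[1:].sum()
        f_rest = math.sqrt(max(rest_target, 1e-12 * sub_tot) / rest)
        for M, f0, fr in ((Z, f_shared, f_rest), (ua, f_rest, f_rest)):
            gm = M[~sub].mean(axis=0)
            scale = np.full(M.shape[1], fr)
            scale[0] = f0
            M[~sub] = gm + scale * (M[~sub] - gm)
        scores = Z * sd                                   # N x 2w

        # lifestyle mean offset along a fixed low-order deformation direction
        direction = np.zeros(2 * w)
        direction[2] = 1.0 / math.sqrt(2)                # warp 2, x
        direction[min(5, 2 * w - 1)] = 1.0 / math.sqrt(2)
        scores[sub] += config.group_mean_offset * direction

        scores3 = scores.reshape(len(species), w, 2)
        dev = np.einsum("kj,njd->nkd", spectrum.eigenvectors, scores3)

        ub = _uniform_basis(template.points)              # 2k x 2
        dev = dev + (ua * math.sqrt(uvar) @ ub.T).reshape(len(species), -1, 2)

        means = template.points[None] + dev
        structures[kind] = StructureSample(
            kind=kind, template=template, sliders=sliders, spectrum=spectrum,
            species_means=means, mean_scores=scores3)
    return SyntheticDataset(config=config, tree=tree, species=species,
                            groups=groups, structures=structures)


def _table1_like_sizes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-species specimen counts with the skewed 2-59 range of a museum
    sample."""
    raw = np.round(np.exp(rng.normal(2.4, 0.7, size=n))).astype(int)
    return np.clip(raw, 2, 59)


def simulate_specimens(dataset: SyntheticDataset,
                       kind: Optional[str] = None) -> SyntheticDataset:
    """Populate ``dataset`` with per-species specimens (and replicates).

    Each specimen is the species mean plus an allometric term (centroid size
    drawn lognormal; slope vector common to all species, optionally rotated
    by 45 degrees for non-subterranean when ``allometry_group_delta`` is set)
    plus isotropic landmark noise, then rotated/translated/scaled at random
    to emulate raw digitized coordinates.  With ``n_replicates = 3``, three
    noisy digitizations of each specimen are emitted.
    """
    config = dataset.config
    kinds = [kind] if kind else list(dataset.structures)
    for kd in kinds:
        st = dataset.structures[kd]
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7, TEMPLATE_KINDS.index(kd)]))
        n_sp = len(dataset.species)
        sizes = (np.full(n_sp, config.n_per_species) if config.balanced
                 else _table1_like_sizes(n_sp, rng))
        w = st.spectrum.n_warps
        # allometric slope vectors in warp-score space, mapped to shape space
        d1 = np.zeros(2 * w)
        d1[0] = 1.0
        d2 = np.zeros(2 * w)
        d2[0] = d2[3 if 2 * w > 3 else 1] = 1.0 / math.sqrt(2)
        E = st.spectrum.eigenvectors
        to_shape = lambda v: np.einsum(
            "kj,jd->kd", E, v.reshape(w, 2))
        slope_common = to_shape(d1) * config.allometry_common
        slope_delta = to_shape(d2) * config.allometry_group_delta

        configs: List[LandmarkConfiguration] = []
        reps: List[List[LandmarkConfiguration]] = [[], [], []]
        rows = []
        for i, sp in enumerate(dataset.species):
            group = dataset.groups[i]
            slope = slope_common + (slope_delta if group == "non-subterranean"
                                    else 0.0)
            for j in range(sizes[i]):
                cs = float(np.exp(rng.normal(math.log(3.0), 0.25)))
                zsize = (math.log(cs) - math.log(3.0)) / 0.25
                shape = (st.species_means[i] + zsize * slope
                         + rng.normal(0.0, config.specimen_noise_sd,
                                      st.species_means[i].shape))
                theta = rng.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
                offset = rng.uniform(-10, 10, size=2)
                raw = shape @ R.T * cs + offset
                sid = f"{sp}_{kd[:3]}_{j + 1:02d}"
                configs.append(LandmarkConfiguration(specimen_id=sid, points=raw))
                rows.append({"specimen_id": sid, "species": sp, "group": group,
                             "structure": kd})
                if config.n_replicates == 3:
                    for r in range(3):
                        noisy = raw + rng.normal(
                            0.0, config.replicate_noise_sd * cs, raw.shape)
                        reps[r].append(LandmarkConfiguration(
                            specimen_id=sid, points=noisy))
        dataset.specimens[kd] = configs
        dataset.specimen_tables[kd] = pd.DataFrame(rows)
        if config.n_replicates == 3:
            dataset.replicates[kd] = reps
    return dataset


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full synthetic dataset: tree, species means, specimens (one call)."""
    tree = simulate_tree(config.n_species, seed=config.seed)
    ds = simulate_species_shapes(config, tree)
    return simulate_specimens(ds)


def simulate_warp_sample(spectrum: BendingSpectrum, exponent: float, n: int,
                         total_var: float = 0.01,
                         seed: Optional[int] = None) -> np.ndarray:
    """i.i.d. shapes around the spectrum's reference with per-warp score
    variance proportional to lambda^(-exponent).

    The expected Bookstein global-integration slope of such a sample is
    exactly ``-exponent``.  Returns (n, k, 2) shapes.
    """
    rng = np.random.default_rng(seed)
    lam = spectrum.eigenvalues
    wvar = lam ** (-exponent)
    wvar = wvar / wvar.sum() * total_var
    scores = rng.standard_normal((n, spectrum.n_warps, 2)) \
        * np.sqrt(wvar / 2.0)[None, :, None]
    dev = np.einsum("kj,njd->nkd", spectrum.eigenvectors, scores)
    return spectrum.reference[None] + dev


def calibrated_replicate_noise(target_percent: float,
                               among_specimen_distance: float,
                               k: int) -> float:
    """Replicate-noise sd giving approximately ``target_percent`` digitization
    error.

    The mean pairwise distance between two replicas with iid N(0, sd^2) noise
    on k 2D landmarks is ~ 2 sd sqrt(k); inverting the error ratio gives
    sd = (target/100) * among-distance / (2 sqrt(k)).
    """
    return target_percent / 100.0 * among_specimen_distance / (2.0 * math.sqrt(k))
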