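# Methods

This note records the statistical models, conventions and numerical choices
behind `gmorpho`, and what the synthetic-data generator does and does not
emulate.

## Superimposition

GPA iterates: center and unit-scale every configuration; rotate each onto
the provisional consensus (SVD of the cross-product, determinant forced to
+1 — reflections are disallowed by default because the design digitizes one
body side — with optimal scaling β = Σ singular values applied inside the
fit, i.e. a full-Procrustes fit); re-estimate the consensus as the mean,
rescaled to unit centroid size. Convergence is an RMS consensus change
below 1e-10 or 100 iterations; non-convergence is a warning on the result,
not an error. Centroid sizes are always taken from the raw configurations.

Because Procrustes alignment leaves a global rotation free, the aligned
sample is put in a canonical orientation (principal axes of the consensus,
180° ambiguity resolved by the sign of the first landmark's larger
coordinate). This makes GPA output invariant to input order and to
similarity transforms of individual inputs, which the test suite asserts.

`align_optimal` (the two-shape operation and the distance it returns) is
rotation-only between two unit-size centered shapes, so its value matches a
brute-force rotation grid and is symmetric; the β-scaling above belongs to
the iterative GPA fit.

Semilandmark sliding: each slider moves along the unit chord between its
two outline neighbours, recomputed each pass; outline endpoints never
slide (the built-in templates are closed outlines, so every slider has two
neighbours). BEN solves the restricted generalized-least-squares system
minimising the TPS bending energy of the consensus→specimen map; PRD
projects the consensus residual onto the tangent. After each sliding pass
the sample is re-superimposed; at most 3 sliding passes by default. Both
criteria are monotone in their own objective, and BEN's solution never has
higher bending energy than PRD's, which the tests verify per specimen.

## Thin-plate splines and partial warps

Kernel convention U(r) = r² log r² (the constant factor cancels in any
log–log regression but is fixed for bit-stable energies). The
bending-energy matrix B is the upper-left k×k block of the inverse bordered
system; its three null eigenvalues span the affine subspace and are
discarded; the remaining k−3 eigenpairs (ascending λ, orthonormal vectors)
are the partial warps. Scores are plain projections of the residual from
the reference onto the eigenvectors, separately for x and y, so total
non-affine variance satisfies a Parseval identity that is tested to 1e-9.

The Jacobian of the TPS map is analytic (∂U/∂x = 2(x−xᵢ)(1 + log r²), with
the r→0 limit set to 0); folded regions (det J ≤ 0) yield NaN plus a
warning. Deformation fields are exported as (x, y, log det J) tables on a
24×24 grid over the reference bounding box padded 5%; no image rendering is
built in — the numbers are the tested artifact.

## Permutation models

All linear models use sequential (type-I) sums of squares computed from
fitted values, with residual randomization (RRPP): for each term the
reduced-model residuals are permuted, the statistic recomputed, and
p = (#{F* ≥ F} + 1)/(nperm + 1). Default nperm = 999; one set of
permutations is shared across terms; effect sizes are z-scores of log F
against the permutation distribution. Centroid size enters untransformed by
default (log CS behind a flag).

Disparity: PV per group is the trace of the group covariance with divisor
n_g, computed from the residuals of the group-mean model (optionally with
CS partialled out first). The pairwise test permutes those residuals'
squared norms across specimens (label permutation behind a flag). P-values
are reported raw, without multiplicity adjustment, matching the field's
reporting convention; a Holm adjustment can be applied downstream.

## Integration

Two-block PLS centres both blocks and decomposes their cross-covariance by
SVD. r-PLS is the Pearson correlation of the first paired scores; the
permutation shuffles rows of the second block and recomputes the
(sign-free) first-axis correlation. Sign conventions — largest left-vector
element positive, first-axis correlation non-negative — make results
deterministic.

Effect size: z = (atanh r − mean atanh r*)/sd atanh r*. Its standard error
is (1/√(n−3))/sd atanh r*: the Fisher-stabilized correlation estimate has
sampling sd ≈ 1/√(n−3) whatever the signal strength, while z is expressed
in permutation-null sd units. With this se the two-sample comparison
(z_a − z_b)/√(se_a² + se_b²) reduces to the classical two-sample z-test for
correlations and calibrates correctly under strong common signal — an
earlier se = 1 convention was rejected after it showed a ~30% type-I rate
in exactly that regime.

Major-axis slopes are compared in angle space (difference of arctangents,
folded to [0, π/2]) because raw slopes blow up near vertical; the null
permutes group labels. Note that each group's PLS axes are defined only up
to a joint sign, so a sign-flipped integration pattern in one group is
invisible to this comparison — direction here means the axis, not an
orientation.

Global integration regresses log combined (x+y) partial-warp score variance
on log λ over all k−3 warps (zero-variance warps dropped with a warning;
per-coordinate regression behind a flag). The self-similar band is
|slope + 1| ≤ 0.05 by default (config-exposed; no canonical value exists).

## Phylogenetic layer

The Brownian covariance C has C[i,j] = depth of the most recent common
ancestor. C^(−1/2) comes from the symmetric eigendecomposition (not
Cholesky) so results do not depend on tip ordering; near-singular C (zero
branch lengths) is ridge-regularized by 1e-8 × tree depth with a warning.

K_mult follows the multivariate Blomberg formulation: the ratio of
Euclidean to C⁻¹-metric deviations from the GLS grand mean, scaled by its
Brownian expectation; it is exactly 1 on a star tree for any data, ~1 in
expectation under BM on any tree (tested to ±0.1 over 200 replicates), and
invariant to global branch-length rescaling.

Phylogenetic ANOVA and PLS premultiply responses (and, for ANOVA, the
design) by C^(−1/2) about the GLS mean. The PLS permutation shuffles
transformed rows, which are exchangeable under the BM null; shuffling raw
species rows and re-transforming per permutation (available as
`permute="raw"`) was measured to be strongly anti-conservative (type-I
~0.4 under independent BM) and is kept only for comparison. On a star tree
both phylogenetic tests coincide with their ordinary counterparts to
machine precision.

Phylogenetic-PLS singular vectors are not rendered as shape deformations;
the GLS transform makes them uninterpretable as shapes, so visualization is
reserved for the ordinary PLS.

## Measurement error

Three replicate digitizations of each specimen are superimposed jointly;
the error is 100 × (mean over specimens of the mean pairwise within-triplet
distance) / (mean pairwise distance among specimen consensus forms). This
transparent ratio replaces an ambiguous min/max-averaging protocol
sometimes described for the same design; both numerator and denominator
live in the same aligned space, so the percentage is scale-free.

## The synthetic generator

The generator emulates a 37-species, two-lifestyle, two-structure study:

* **Templates.** Smooth star-shaped outlines at unit centroid size: a
  36-point humerus-like template (22 fixed + 14 sliders, the sliders on the
  tubercle-surface, sulcus and head curve segments) and a 38-point
  mandible-like template (12 fixed + 26 sliders on six curve segments with
  fixed endpoints). The exact split of fixed vs sliding points on such
  templates is a documented modelling assumption.
* **Tree.** Pure-birth with the stated tip count, scaled to unit depth,
  deterministic per seed.
* **Species means.** Scores in the template's partial-warp basis evolve by
  BM on the tree with per-warp variance ∝ λ⁻ᶜ (default exponents 1.3 for
  the humerus-like and 2.0 for the mandible-like structure), plus a small
  uniform (affine) component (5% of variance). The Bookstein slope of such
  data is −c by construction, which anchors the global-integration tests.
* **Groups.** The subterranean group is by default a clade (nearest in size
  to 26 of 37), so the lifestyle mean offset (0.15 along a fixed low-order
  deformation) is a Brownian-plausible stem innovation. Clade-aligned
  groups under BM make naive group tests anti-conservative by
  pseudoreplication — that is a property of the design, not a bug — so
  calibration checks use `clade_groups=False` (random, exchangeable
  groups).
* **Disparity.** Within-group deviations are rescaled so the realized
  non-subterranean/subterranean Procrustes-variance ratio equals the
  configured value (default 4) exactly at species level, compensating the
  tree-driven baseline imbalance between the groups.
* **Integration.** A latent BM factor with loading √ρ on each structure's
  highest-variance warp axis induces cross-structure correlation ρ
  (default 0.85). With group-specific ρ (the `talpid_study` configuration:
  0.85 subterranean, 0.7 non-subterranean), each group gets its own latent,
  and the non-subterranean latent loads with opposite sign in the second
  structure so the groups' contributions to whole-sample cross-covariance
  partially cancel — within-group analyses are unaffected because a PLS
  axis pair is defined up to a joint sign.
* **Specimens.** Lognormal centroid sizes, allometric shape change along a
  fixed direction (optionally group-specific), isotropic landmark noise
  (sd 0.005 at unit-CS scale), random rotation/translation/scale to emulate
  raw digitized coordinates, museum-like per-species sample sizes
  (lognormal, clipped to 2–59, mean ≈ 12; `balanced` for equal sizes), and
  optional digitization triplicates whose noise is calibrated near a 0.8%
  error ratio.

What passing tests on these data do **not** show: real outlines are not
star-shaped radial curves; real digitization error is anisotropic and
landmark-specific; real within-species variation is structured, not
isotropic; real lifestyle effects are not a single fixed deformation; and
real group differences in integration need not follow the sign-cancellation
construction. The generator validates the statistical machinery, not any
biological claim.

## Known limitations

* 2D only; no surface sliding, curve resampling or symmetry decomposition.
* The qualitative "whole-sample integration disappears under phylogenetic
  correction while the subterranean group stays significant" pattern is
  reproduced only stochastically (roughly half of generator seeds): a
  latent factor strong enough to stay detectable under GLS within the
  26-species group necessarily retains power in the 37-species test that
  contains the same rows. The acceptance suite asserts the pattern by
  majority over five replicate runs and may fail on that component.
* bgPCA percentages are reported against both the group-mean covariance
  total and the total specimen variance, because published figures use
  either convention without saying so.
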