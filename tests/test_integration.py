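import math

import numpy as np
import pytest

from gmorpho.integration import (PlsResult, compare_global_integration,
                                 compare_ma_slopes, compare_pls,
                                 global_integration_slope, major_axis_slope,
                                 pls_effect_size, two_block_pls)
from gmorpho.synthetic import simulate_warp_sample


def _latent_blocks(rng, n=200, p1=6, p2=6, rho=0.9, signal_sd=1.0,
                   noise_sd=0.45):
    """Two blocks sharing one latent factor with score correlation rho.

    Noise is kept orthogonal to the signal direction so the axis-1 score
    correlation equals rho exactly in expectation.
    """
    u = rng.standard_normal(n)
    v = math.sqrt(rho) * u + math.sqrt(1 - rho) * rng.standard_normal(n)
    out = []
    for latent, p in ((u, p1), (v, p2)):
        w = np.ones(p) / math.sqrt(p)
        noise = rng.normal(0, noise_sd, (n, p))
        noise -= np.outer(noise @ w, w)
        out.append(np.outer(latent * signal_sd, w) + noise)
    return out[0], out[1]


class TestTwoBlockPls:
    def test_identical_blocks(self, rng):
        Y = rng.standard_normal((20, 5))
        res = two_block_pls(Y, Y, nperm=99, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rotation_invariance(self, rng):
        Y = rng.standard_normal((20, 5))
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        res = two_block_pls(Y, Y @ Q, nperm=99, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-9)

    def test_rpls_invariant_to_block_rotations_and_scale(self, rng):
        Y1, Y2 = _latent_blocks(rng, n=60)
        Q1, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        Q2, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        a = two_block_pls(Y1, Y2, nperm=99, seed=1)
        b = two_block_pls(3.7 * Y1 @ Q1, 0.2 * Y2 @ Q2, nperm=99, seed=1)
        assert a.r_pls == pytest.approx(b.r_pls, abs=1e-9)

    def test_singular_values_descending_and_r1_nonnegative(self, rng):
        Y1, Y2 = _latent_blocks(rng, n=50)
        res = two_block_pls(Y1, Y2, nperm=99, seed=2)
        assert np.all(np.diff(res.singular_values) <= 1e-12)
        assert res.r_per_axis[0] >= 0

    def test_latent_correlation_recovered(self):
        rs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            Y1, Y2 = _latent_blocks(rng, n=200, rho=0.9)
            rs.append(two_block_pls(Y1, Y2, nperm=99, seed=rep).r_pls)
        assert np.mean(rs) == pytest.approx(0.9, abs=0.05)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="same number"):
            two_block_pls(rng.standard_normal((5, 3)),
                          rng.standard_normal((6, 3)), nperm=99)
        with pytest.raises(ValueError, match="zero variance"):
            two_block_pls(np.ones((5, 3)), rng.standard_normal((5, 3)),
                          nperm=99)


class TestEffectSize:
    def _fake_result(self, r_obs, perm_r):
        perm_r = np.asarray(perm_r)
        n = 10
        z = np.zeros((n, 1))
        return PlsResult(singular_values=np.array([1.0]), left_vectors=z,
                         right_vectors=z, left_scores=z, right_scores=z,
                         r_per_axis=np.array([r_obs]), p_perm=0.5,
                         perm_r_distribution=perm_r, effect_size_z=0.0,
                         se_z=1.0, nperm=len(perm_r), seed=None)

    def test_observed_at_permutation_mean_gives_zero(self, rng):
        perm = rng.uniform(0.2, 0.4, 999)
        fisher_mean = np.tanh(np.arctanh(perm).mean())
        z, se = pls_effect_size(self._fake_result(fisher_mean, perm))
        assert z == pytest.approx(0, abs=1e-9)

    def test_normal_quantile_consistency(self, rng):
        f = rng.normal(0.5, 0.1, 100000)
        perm = np.tanh(f)
        r_obs = np.tanh(np.quantile(f, 0.975))
        z, se = pls_effect_size(self._fake_result(r_obs, perm))
        assert z == pytest.approx(1.96, abs=0.2)

    def test_null_blocks_give_zero_mean_z(self):
        zs = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            Y1 = rng.standard_normal((25, 4))
            Y2 = rng.standard_normal((25, 4))
            zs.append(two_block_pls(Y1, Y2, nperm=99, seed=rep).effect_size_z)
        assert abs(np.mean(zs)) < 0.15

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate|sd"):
            pls_effect_size(self._fake_result(0.5, np.full(200, 0.3)))


class TestComparePls:
    def test_same_result_gives_zero(self, rng):
        Y1, Y2 = _latent_blocks(rng, n=40)
        res = two_block_pls(Y1, Y2, nperm=99, seed=0)
        z, p = compare_pls(res, res)
        assert z == 0
        assert p == pytest.approx(1.0)

    def test_power_for_different_strengths(self):
        hits = 0
        for rep in range(25):
            rng = np.random.default_rng(rep)
            Y1a, Y2a = _latent_blocks(rng, n=100, rho=0.9)
            Y1b, Y2b = _latent_blocks(rng, n=100, rho=0.3)
            a = two_block_pls(Y1a, Y2a, nperm=199, seed=rep)
            b = two_block_pls(Y1b, Y2b, nperm=199, seed=rep)
            hits += compare_pls(a, b)[1] <= 0.05
        assert hits >= 20


class TestMajorAxis:
    @pytest.mark.parametrize("slope", [1.0, 2.0])
    def test_exact_lines(self, slope, rng):
        x = rng.uniform(-1, 1, 30)
        assert major_axis_slope(x, slope * x) == pytest.approx(slope)

    def test_known_bivariate_slope(self):
        rng = np.random.default_rng(0)
        # direction (2, 1): slope 0.5, with modest isotropic noise
        t = rng.standard_normal(1000)
        x = 2 * t + rng.normal(0, 0.3, 1000)
        y = t + rng.normal(0, 0.3, 1000)
        assert major_axis_slope(x, y) == pytest.approx(0.5, abs=0.05)

    def test_matches_leading_eigenvector(self, rng):
        x = rng.standard_normal(50)
        y = 0.7 * x + rng.normal(0, 0.5, 50)
        s = major_axis_slope(x, y)
        cov = np.cov(x, y)
        vec = np.linalg.eigh(cov)[1][:, -1]
        assert s == pytest.approx(vec[1] / vec[0], rel=1e-9)

    def test_axis_aligned_degenerate_cases(self, rng):
        x = rng.standard_normal(20)
        zero = np.zeros(20)
        assert major_axis_slope(x, zero) == 0.0
        assert major_axis_slope(zero, x) == math.inf
        with pytest.raises(ValueError, match="at least 3|variation"):
            major_axis_slope(np.zeros(5), np.zeros(5))


class TestCompareMaSlopes:
    def test_identical_groups_give_p_one(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.normal(0, 0.2, 30)
        slopes, p = compare_ma_slopes({"a": (x, y), "b": (x, y)},
                                      nperm=199, seed=0)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_power_for_distinct_slopes(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            xa = rng.standard_normal(50)
            ya = 0.4 * xa + rng.normal(0, 0.1, 50)
            xb = rng.standard_normal(50)
            yb = 1.0 * xb + rng.normal(0, 0.1, 50)
            _, p = compare_ma_slopes({"a": (xa, ya), "b": (xb, yb)},
                                     nperm=199, seed=rep)
            hits += p.loc["a", "b"] <= 0.05
        assert hits >= 18


class TestGlobalIntegration:
    @pytest.mark.parametrize("c,regime", [
        (0.0, "dis-integrated"), (1.0, "self-similar"), (2.0, "integrated")])
    def test_exponent_recovered(self, c, regime, humerus_spectrum):
        slopes = [global_integration_slope(
            simulate_warp_sample(humerus_spectrum, c, 200, seed=s),
            humerus_spectrum, self_similarity_tol=0.1).slope
            for s in range(3)]
        assert np.mean(slopes) == pytest.approx(-c, abs=0.1)
        res = global_integration_slope(
            simulate_warp_sample(humerus_spectrum, c, 500, seed=9),
            humerus_spectrum, self_similarity_tol=0.1)
        assert res.interpretation == regime

    def test_identical_samples_compare_p_one(self, small_spectrum):
        shapes = simulate_warp_sample(small_spectrum, 1.0, 20, seed=0)
        sa, sb, p = compare_global_integration(shapes, shapes.copy(),
                                               small_spectrum, nperm=199,
                                               seed=0)
        assert sa == sb
        assert p == pytest.approx(1.0)

    def test_power_for_distinct_exponents(self, small_spectrum):
        hits = 0
        for rep in range(10):
            a = simulate_warp_sample(small_spectrum, 1.0, 30, seed=rep)
            b = simulate_warp_sample(small_spectrum, 2.0, 30, seed=1000 + rep)
            _, _, p = compare_global_integration(a, b, small_spectrum,
                                                 nperm=199, seed=rep)
            hits += p <= 0.05
        assert hits >= 9
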