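import numpy as np
import pytest

from gmorpho.geometry import centroid_size, gpa, procrustes_distance
from gmorpho.integration import two_block_pls
from gmorpho.linear_models import morphological_disparity, procrustes_anova
from gmorpho.synthetic import (GeneratorConfig, make_template,
                               simulate_dataset, simulate_species_shapes,
                               simulate_specimens, simulate_tree,
                               simulate_warp_sample)


class TestTemplates:
    @pytest.mark.parametrize("kind,k,n_sliders", [
        ("humerus36", 36, 14), ("mandible38", 38, 26)])
    def test_counts_and_unit_cs(self, kind, k, n_sliders):
        tpl, sliders = make_template(kind)
        assert tpl.k == k
        assert len(sliders) == n_sliders
        assert centroid_size(tpl.points) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["humerus36", "mandible38"])
    def test_sliders_flank_their_point(self, kind):
        tpl, sliders = make_template(kind)
        k = tpl.k
        for b, s, a in sliders.rows:
            assert b == (s - 1) % k
            assert a == (s + 1) % k

    @pytest.mark.parametrize("kind", ["humerus36", "mandible38"])
    def test_outline_star_shaped(self, kind):
        # radius from centroid strictly positive: non-self-intersecting
        tpl, _ = make_template(kind)
        r = np.linalg.norm(tpl.points - tpl.points.mean(axis=0), axis=1)
        assert r.min() > 0.01

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown"):
            make_template("femur")


class TestTree:
    def test_tip_count_and_unit_depth(self):
        tree = simulate_tree(37, seed=4)
        C = tree.covariance()
        assert tree.n_tips == 37
        np.testing.assert_allclose(C.diagonal(), 1.0, atol=1e-9)

    def test_deterministic_per_seed(self):
        a = simulate_tree(20, seed=9).as_newick()
        b = simulate_tree(20, seed=9).as_newick()
        c = simulate_tree(20, seed=10).as_newick()
        assert a == b
        assert a != c

    def test_three_tips_two_internal_nodes(self):
        tree = simulate_tree(3, seed=0)
        internal = sum(1 for n in tree.tree.preorder_node_iter()
                       if not n.is_leaf())
        assert internal == 2


class TestSpeciesShapes:
    def test_full_determinism(self):
        cfg = GeneratorConfig(seed=21, balanced=True, n_per_species=3,
                              n_replicates=3)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        for kind in cfg.templates:
            np.testing.assert_array_equal(
                a.structures[kind].species_means,
                b.structures[kind].species_means)
            for ca, cb in zip(a.specimens[kind], b.specimens[kind]):
                assert ca.specimen_id == cb.specimen_id
                np.testing.assert_array_equal(ca.points, cb.points)
            for ra, rb in zip(a.replicates[kind], b.replicates[kind]):
                for ca, cb in zip(ra, rb):
                    np.testing.assert_array_equal(ca.points, cb.points)

    def test_disparity_ratio_realized_exactly_at_species_level(self):
        for seed in (3, 4):
            cfg = GeneratorConfig(seed=seed, disparity_ratio=4.0)
            ds = simulate_species_shapes(cfg, simulate_tree(37, seed=seed))
            for kind in cfg.templates:
                res = morphological_disparity(
                    ds.structures[kind].species_means, ds.groups,
                    nperm=99, seed=0)
                pv = dict(zip(res.groups, res.group_variances))
                ratio = pv["non-subterranean"] / pv["subterranean"]
                assert ratio == pytest.approx(4.0, rel=0.01)

    def test_rho_one_gives_perfect_latent_correlation(self):
        cfg = GeneratorConfig(seed=7, integration_rho=1.0,
                              group_mean_offset=0.0)
        ds = simulate_species_shapes(cfg, simulate_tree(37, seed=7))
        a = ds.structures["humerus36"].mean_scores[:, 0, 0]
        b = ds.structures["mandible38"].mean_scores[:, 0, 0]
        assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_rho_zero_no_integration_under_phylogenetic_test(self):
        # independent BM inflates the naive r-PLS (tree pseudoreplication);
        # the phylogenetic test is the calibrated one under this generator
        from gmorpho.phylo import phylo_pls
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = GeneratorConfig(seed=seed, integration_rho=0.0,
                                  group_mean_offset=0.0, disparity_ratio=1.0)
            tree = simulate_tree(37, seed=seed)
            ds = simulate_species_shapes(cfg, tree)
            Y1 = ds.structures["humerus36"].species_means.reshape(37, -1)
            Y2 = ds.structures["mandible38"].species_means.reshape(37, -1)
            res = phylo_pls(Y1, Y2, tree, ds.species, nperm=99, seed=seed)
            hits += res.p_perm > 0.05
        assert hits >= n_rep - 2

    def test_null_config_gives_nonsignificant_anova(self):
        # exchangeable (random) groups: offsets off -> calibrated ANOVA
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            cfg = GeneratorConfig(seed=seed, group_mean_offset=0.0,
                                  disparity_ratio=1.0, clade_groups=False)
            ds = simulate_species_shapes(cfg, simulate_tree(37, seed=seed))
            res = procrustes_anova(ds.structures["humerus36"].species_means,
                                   ds.groups, nperm=99, seed=seed)
            hits += res.term("groups").p_perm > 0.05
        assert hits >= n_rep - 2

    def test_group_offset_separates_groups(self):
        cfg = GeneratorConfig(seed=2)
        ds = simulate_species_shapes(cfg, simulate_tree(37, seed=2))
        res = procrustes_anova(ds.structures["humerus36"].species_means,
                               ds.groups, nperm=999, seed=0)
        assert res.term("groups").p_perm == pytest.approx(0.001)


class TestSpecimens:
    def test_noise_free_specimens_equal_species_mean_shape(self):
        cfg = GeneratorConfig(seed=13, specimen_noise_sd=0.0,
                              allometry_common=0.0, balanced=True,
                              n_per_species=3, templates=("humerus36",))
        ds = simulate_dataset(cfg)
        table = ds.specimen_tables["humerus36"]
        for i in (0, 5, 20):
            row = table.iloc[i]
            sp_i = ds.species.index(row.species)
            d = procrustes_distance(ds.specimens["humerus36"][i].points,
                                    ds.structures["humerus36"]
                                    .species_means[sp_i])
            assert d < 1e-9

    def test_specimen_table_consistent(self):
        cfg = GeneratorConfig(seed=1, balanced=True, n_per_species=4)
        ds = simulate_dataset(cfg)
        t = ds.specimen_table()
        assert set(t.structure) == set(cfg.templates)
        assert set(t.group) == {"subterranean", "non-subterranean"}
        assert t.groupby(["specimen_id", "structure"]).size().max() == 1

    def test_table1_like_sizes_in_range(self):
        cfg = GeneratorConfig(seed=3, templates=("humerus36",))
        ds = simulate_dataset(cfg)
        sizes = ds.specimen_tables["humerus36"].groupby("species").size()
        assert sizes.min() >= 2
        assert sizes.max() <= 59
        assert len(sizes) == 37

    def test_allometry_direction_recovered(self):
        from gmorpho.linear_models import Term, rrpp_model
        cfg = GeneratorConfig(seed=5, n_species=10, n_subterranean=5,
                              balanced=True, n_per_species=20,
                              allometry_common=0.05, specimen_noise_sd=0.002,
                              templates=("humerus36",))
        ds = simulate_dataset(cfg)
        aligned = gpa(ds.specimens["humerus36"])
        table = ds.specimen_tables["humerus36"]
        Y = aligned.shapes.reshape(aligned.n, -1)
        cs = np.log(aligned.centroid_sizes)
        x = cs - cs.mean()
        beta = x @ (Y - Y.mean(0)) / (x @ x)
        st = ds.structures["humerus36"]
        d1 = np.zeros(2 * st.spectrum.n_warps)
        d1[0] = 1.0
        truth = np.einsum("kj,jd->kd", st.spectrum.eigenvectors,
                          d1.reshape(-1, 2)).ravel()
        # correlate estimated allometric vector with the generating one,
        # allowing for the GPA orientation of the aligned sample
        est = beta.reshape(-1, 2)
        best = 0.0
        for flip in (1.0, -1.0):
            for theta in np.linspace(0, 2 * np.pi, 720, endpoint=False):
                R = np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]]) * flip
                v = (est @ R.T).ravel()
                c = abs(np.corrcoef(v, truth)[0, 1])
                best = max(best, c)
        assert best >= 0.95


def test_warp_sample_expected_slope(small_spectrum):
    from gmorpho.integration import global_integration_slope
    shapes = simulate_warp_sample(small_spectrum, 1.5, 400, seed=3)
    res = global_integration_slope(shapes, small_spectrum)
    assert res.slope == pytest.approx(-1.5, abs=0.15)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(integration_rho=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(disparity_ratio=0.0)
    with pytest.raises(ValueError):
        GeneratorConfig(n_replicates=2)
    with pytest.raises(ValueError):
        GeneratorConfig(n_species=10, n_subterranean=10)
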