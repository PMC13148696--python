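import numpy as np
import pytest

from nichescape import (build_weights, fit_mve, make_landscape, make_scenario,
                        morans_i, sample_occurrences, simulate_niche_evolution,
                        simulate_ou_on_tree, simulate_tree)
from nichescape.evolution import tree_covariance


class TestLandscape:
    def test_zero_gradient_gives_flat_row_means(self):
        land = make_landscape(60, 60, 2, gradient_strength=0.0, seed=1)
        temp = land.layers["temperature"]
        row_means = temp.mean(axis=1)
        assert row_means.max() - row_means.min() < 3 * temp.std()
        # and no systematic monotone trend
        assert abs(np.corrcoef(np.arange(60), row_means)[0, 1]) < 0.9

    def test_gradient_orients_temperature(self):
        land = make_landscape(80, 40, 2, gradient_strength=15.0, seed=2)
        temp = land.layers["temperature"]
        assert temp[:10].mean() > temp[-10:].mean() + 5  # warm "tropical" edge

    def test_layers_spatially_autocorrelated(self):
        land = make_landscape(60, 60, 2, autocorr_range_km=8.0, seed=3)
        # Moran's I on a 12x12 subsample of cells
        rs = np.arange(0, 60, 5)
        cent, vals = [], []
        for r in rs:
            for c in rs:
                x, y = land.transform.cell_center(r, c)
                cent.append([x, y])
                vals.append(land.layers["temperature"][r, c])
        w = build_weights(np.array(cent), scheme="W_row", threshold_km=5.01)
        I, e, p = morans_i(np.array(vals), w, n_perm=99, seed=0)
        assert I > e
        assert p <= 0.05

    def test_seeds_differ_but_marginals_agree(self):
        a = make_landscape(80, 80, 2, seed=10)
        b = make_landscape(80, 80, 2, seed=11)
        assert not np.array_equal(a.layers["temperature"], b.layers["temperature"])
        assert a.layers["temperature"].mean() == pytest.approx(
            b.layers["temperature"].mean(), abs=1.0)
        assert a.layers["temperature"].std() == pytest.approx(
            b.layers["temperature"].std(), rel=0.3)

    def test_precipitation_bimodal(self):
        land = make_landscape(100, 100, 2, seed=4)
        p = land.layers["precipitation"].ravel()
        lo, hi = np.quantile(p, [0.2, 0.8])
        mid = (lo + hi) / 2
        # wet and dry regimes both well populated, middle sparse
        n_mid = ((p > mid - 80) & (p < mid + 80)).mean()
        n_lo = (p <= lo).mean()
        assert n_mid < n_lo


class TestSimulateTree:
    def test_three_tips_counting(self):
        tree = simulate_tree(3, seed=0)
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 2

    def test_ultrametric_height_one(self):
        tree = simulate_tree(12, seed=5)
        C, _ = tree_covariance(tree)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)

    def test_lineages_through_time_match_independent_simulator(self):
        # two-implementation agreement on E[#lineages at half height]
        def count_at_half(tree):
            C, _ = tree_covariance(tree)
            n = C.shape[0]
            depths = sorted(set(np.round(C[np.triu_indices(n, 1)], 12)))
            # lineages at time 0.5 = 1 + number of splits before 0.5
            splits = [d for d in depths if d < 0.5]
            return 1 + len(splits)

        got = np.mean([count_at_half(simulate_tree(16, seed=s)) for s in range(100)])

        # independent oracle: bare exponential-race Yule on 16 tips
        rng = np.random.default_rng(999)
        oracle = []
        for _ in range(2000):
            times, k, t = [], 1, 0.0
            while k < 16:
                t += rng.exponential(1 / k)
                times.append(t)
                k += 1
            t_end = t + rng.exponential(1 / 16)
            t0 = times[0]
            height = t_end - t0
            splits = sum(1 for x in times[1:] if (x - t0) / height < 0.5)
            oracle.append(2 + splits)  # the root split itself leaves 2 lineages
        assert got == pytest.approx(np.mean(oracle), abs=0.6)


class TestOUSimulation:
    def test_zero_variance_keeps_root_value(self, tree10):
        vals = simulate_ou_on_tree(tree10, 0.0, 0.0, 0.0, 3.5, seed=1)
        assert all(v == pytest.approx(3.5) for v in vals.values())

    def test_tip_variance_matches_ou_marginal(self, tree10):
        alpha, sigma2 = 3.0, 1.0
        sims = np.array([
            [v for _, v in sorted(simulate_ou_on_tree(
                tree10, alpha, sigma2, 0.0, 0.0, seed=rep).items())]
            for rep in range(400)])
        v = sims.var(axis=0, ddof=1).mean()
        expected = sigma2 / (2 * alpha) * (1 - np.exp(-2 * alpha))  # t = 1
        assert v == pytest.approx(expected, rel=0.10)

    def test_bm_limit_variance_grows_linearly(self, tree10):
        sims = np.array([
            [v for _, v in sorted(simulate_ou_on_tree(
                tree10, 0.0, 2.0, 0.0, 0.0, seed=rep).items())]
            for rep in range(400)])
        v = sims.var(axis=0, ddof=1).mean()
        assert v == pytest.approx(2.0, rel=0.15)  # sigma2 * t with t = 1


class TestNicheEvolution:
    def test_all_volumes_positive(self, tree10):
        niches = simulate_niche_evolution(tree10, np.zeros(2),
                                          {"alpha": 1.0, "sigma2": 1.0}, seed=2)
        assert all(e.volume > 0 for e in niches.values())

    def test_breadth_coupling_orders_volumes(self, tree10):
        niches = simulate_niche_evolution(
            tree10, np.zeros(2), {"alpha": 0.2, "sigma2": 3.0}, seed=3,
            breadth_model={"axis": 0, "slope": 0.8, "center": 0.0},
            sd_lognorm_sigma=0.01)
        sp = sorted(niches)
        c0 = np.array([niches[s].centroid[0] for s in sp])
        vol = np.array([niches[s].volume for s in sp])
        rho = np.corrcoef(c0, np.log(vol))[0, 1]
        assert rho > 0.8


class TestSampleOccurrences:
    def test_points_inside_generating_ellipsoid(self, landscape):
        from nichescape import extract_env, fit_pca, project_pca
        pca = fit_pca(landscape, 2)
        pc = project_pca(pca, landscape)
        niches = simulate_niche_evolution(simulate_tree(4, seed=1), np.zeros(2),
                                          {"alpha": 1.0, "sigma2": 0.5}, seed=4)
        ell = list(niches.values())[0]
        occ = sample_occurrences(ell, pc, 40, seed=5)
        env = extract_env(occ, pc)
        assert ell.contains(env).all()
        assert len(occ) == 40

    def test_mve_roundtrip_recovers_centroid(self, landscape):
        from nichescape import extract_env, fit_pca, project_pca
        pca = fit_pca(landscape, 2)
        pc = project_pca(pca, landscape)
        ell = None
        niches = simulate_niche_evolution(simulate_tree(6, seed=2), np.zeros(2),
                                          {"alpha": 0.5, "sigma2": 0.3}, seed=6)
        ell = max(niches.values(), key=lambda e: e.volume)
        occ = sample_occurrences(ell, pc, 500, seed=7)
        env = extract_env(occ, pc)
        fitted = fit_mve(env, coverage=0.95, seed=8)
        axis_lengths = np.sqrt(np.linalg.eigvalsh(ell.covariance) * ell.radius2)
        tol = 0.5 * axis_lengths.min()
        assert np.linalg.norm(fitted.centroid - ell.centroid) < tol


class TestScenario:
    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="preset"):
            make_scenario("bogus", 0)

    def test_determinism_same_master_seed(self):
        a = make_scenario("neutral", 13, n_species=8, n_rows=60, n_cols=60)
        b = make_scenario("neutral", 13, n_species=8, n_rows=60, n_cols=60)
        np.testing.assert_array_equal(a.landscape.layers["temperature"],
                                      b.landscape.layers["temperature"])
        assert [o.records for o in a.occurrences] == [o.records for o in b.occurrences]
        np.testing.assert_array_equal(a.true_root, b.true_root)

    def test_every_species_sampled(self):
        sc = make_scenario("breadth_gradient", 3, n_species=10, n_rows=80, n_cols=80)
        tips = {l.taxon.label for l in sc.tree.leaf_node_iter()}
        assert {o.species_id for o in sc.occurrences} == tips
        assert all(len(o) == 60 for o in sc.occurrences)

    def test_breadth_gradient_builds_negative_breadth_richness_association(self):
        from nichescape import build_pam, map_property, predict_presence, richness
        from nichescape.ellipsoid import RangeMap
        from scipy.stats import spearmanr
        sc = make_scenario("breadth_gradient", 5, n_species=20, n_rows=120, n_cols=120)
        ranges = []
        for sp, ell in sorted(sc.true_niches.items()):
            pres = predict_presence(ell, sc.pc_stack)
            cells = {(int(r), int(c)) for r, c in zip(*np.nonzero(pres == 1))}
            ranges.append(RangeMap(species_id=sp, cells=cells))
        pam = build_pam(ranges, sc.landscape, grid_res_km=10.0)
        rich = richness(pam)
        vols = {sp: e.volume for sp, e in sc.true_niches.items()}
        mean_nb = map_property(pam, vols)
        keep = (rich > 0) & np.isfinite(mean_nb)
        rho, _ = spearmanr(rich[keep], mean_nb[keep])
        assert rho < 0

    def test_scenario_save_writes_text_bundle(self, tmp_path):
        sc = make_scenario("neutral", 21, n_species=6, n_rows=40, n_cols=40)
        sc.save(tmp_path / "bundle")
        assert (tmp_path / "bundle" / "tree.nwk").exists()
        assert (tmp_path / "bundle" / "occurrences.csv").exists()
        assert (tmp_path / "bundle" / "truth.json").exists()
        assert (tmp_path / "bundle" / "landscape" / "temperature.asc").exists()
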