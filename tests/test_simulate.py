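import numpy as np
import pytest
from scipy import stats

from betascape import betadiv
from betascape.nulls import randomize_richness
from betascape.simulate import (Landscape, SimulationParams,
                                assemble_communities, build_landscape,
                                evolve_niche_traits, generate_dataset,
                                normalize_depth, simulate_phylogeny)


class TestSimulatePhylogeny:
    def test_two_species_cherry_ultrametric(self):
        phy = simulate_phylogeny(2, 1.0, 0.0, rng=1)
        assert phy.n_tips == 2
        depths = [lf.distance_from_root()
                  for lf in phy.tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)

    def test_ultrametric_with_extinction(self):
        phy = simulate_phylogeny(30, 1.0, 0.4, rng=2)
        depths = [lf.distance_from_root()
                  for lf in phy.tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_polytomy_collapse_preserves_depths(self):
        phy = simulate_phylogeny(60, 1.0, 0.0, rng=3, polytomy_epsilon=0.1)
        depths = [lf.distance_from_root()
                  for lf in phy.tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        assert phy.n_internal < 59  # some nodes collapsed into polytomies

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_phylogeny(5, 0.5, 0.5, rng=0)

    def test_pure_birth_growth_rate(self):
        """E[tips] of a Yule process after time t is e^(b t)."""
        import dendropy
        from dendropy.model import birthdeath
        import random
        b, t_max, reps = 1.0, 1.5, 400
        rng = random.Random(0)
        tips = []
        for _ in range(reps):
            tr = birthdeath.birth_death_tree(
                birth_rate=b, death_rate=0.0, max_time=t_max, rng=rng)
            tips.append(len(tr.leaf_nodes()))
        expected = np.exp(b * t_max)
        se = np.std(tips, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(tips) - expected) < 4 * se + 0.1


class TestNicheEvolution:
    def test_zero_rate_perfect_conservatism(self):
        phy = simulate_phylogeny(12, 1.0, 0.0, rng=4)
        opt = evolve_niche_traits(phy, {"climate": 0.0}, rng=0)
        assert (opt["climate"] == 0.0).all()

    def test_tip_variance_matches_brownian_identity(self):
        """Var(tip) across replicates = sigma^2 * root-to-tip depth."""
        phy = normalize_depth(simulate_phylogeny(8, 1.0, 0.0, rng=5))
        s2 = 2.0
        reps = 400
        vals = np.array([
            evolve_niche_traits(phy, {"x": s2}, rng=r)["x"].to_numpy()
            for r in range(reps)])
        per_tip_var = vals.var(axis=0, ddof=1)
        # chi-square CI for a variance at 400 reps is about +/- 20%
        assert np.all(per_tip_var > s2 * 0.7)
        assert np.all(per_tip_var < s2 * 1.4)

    def test_sisters_covary_more_than_distant_tips(self):
        phy = normalize_depth(simulate_phylogeny(16, 1.0, 0.0, rng=6))
        d = phy.cophenetic()
        labels = list(phy.tip_labels)
        i, j = np.unravel_index(np.argmin(d + np.eye(len(d)) * 99), d.shape)
        a, b = np.unravel_index(np.argmax(d), d.shape)
        reps = 200
        vals = np.array([
            evolve_niche_traits(phy, {"x": 1.0}, rng=r)["x"].to_numpy()
            for r in range(reps)])
        cov_close = np.cov(vals[:, i], vals[:, j])[0, 1]
        cov_far = np.cov(vals[:, a], vals[:, b])[0, 1]
        assert cov_close > cov_far


class TestLandscape:
    def test_single_sinusoid_noise_free_exact(self):
        params = SimulationParams(
            n_plots=25, n_species=50, target_richness=10, noise_sd=0.0,
            n_variables={"climate": 1, "soil": 1, "geomorphology": 1},
            between_class_correlation=0.0)
        land = build_landscape(params, rng=0)
        clim = land.environment.matrix_of("climate")[:, 0]
        lat = land.latent["climate"].to_numpy()
        # noise-free observed variable is an affine map of the latent field
        r = abs(np.corrcoef(clim, lat)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_zero_correlation_configuration(self):
        params = SimulationParams(n_plots=200, n_species=50,
                                  target_richness=10,
                                  between_class_correlation=0.0)
        land = build_landscape(params, rng=1)
        r = np.corrcoef(land.latent["climate"], land.latent["soil"])[0, 1]
        assert abs(r) < 3 / np.sqrt(200)

    def test_requested_correlation_realized(self):
        params = SimulationParams(n_plots=300, n_species=50,
                                  target_richness=10,
                                  between_class_correlation=0.6)
        land = build_landscape(params, rng=2)
        r = np.corrcoef(land.latent["climate"], land.latent["soil"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.15)

    def test_gradient_wavelength_recovered_spectrally(self):
        """Periodogram of a noise-free field along x peaks within one bin
        of the configured wavelength."""
        wl_true = 55.0
        params = SimulationParams(
            n_plots=128, n_species=50, target_richness=10, noise_sd=0.0,
            grid=False, extent_km=(220.0, 1.0),
            gradient_wavelengths={"climate": (wl_true,), "soil": (20.0,),
                                  "geomorphology": (80.0,)},
            between_class_correlation=0.0)
        land = build_landscape(params, rng=3)
        from scipy.signal import lombscargle
        x = land.coordinates.x
        y = land.latent["climate"].to_numpy()
        wls = np.geomspace(440, 5, 300)
        power = lombscargle(x, y - y.mean(), 2 * np.pi / wls)
        wl_hat = wls[np.argmax(power)]
        assert wl_hat == pytest.approx(wl_true, rel=0.15)


class TestAssembly:
    def test_neutral_limit_matches_richness_null(self):
        """w = 0, delta = inf assembly is the equiprobable
        richness-preserving null: per-species inclusion frequencies pass a
        chi-square uniformity test."""
        params = SimulationParams(n_plots=3, n_species=24,
                                  target_richness=8, filter_strength=0.0,
                                  dispersal_scale=np.inf)
        phy = normalize_depth(simulate_phylogeny(24, 1.0, 0.0, rng=7))
        opt = evolve_niche_traits(phy, {"climate": 1.0, "soil": 1.0}, rng=0)
        land = build_landscape(params, rng=1)
        rng = np.random.default_rng(2)
        counts = np.zeros(24)
        n_draws = 2000
        src = None
        for _ in range(n_draws):
            table, src = assemble_communities(phy, opt, land, params, rng,
                                              seed_sources=src)
            counts += table.incidence[0]
        expected = np.full(24, counts.sum() / 24)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=23) > 0.01

    def test_strong_filter_picks_nearest_optima(self):
        params = SimulationParams(n_plots=10, n_species=40,
                                  target_richness=5,
                                  filter_strength=200.0,
                                  dispersal_scale=np.inf)
        phy = normalize_depth(simulate_phylogeny(40, 1.0, 0.0, rng=8))
        opt = evolve_niche_traits(phy, {"climate": 1.0, "soil": 1.0}, rng=1)
        land = build_landscape(params, rng=2)
        table, _ = assemble_communities(phy, opt, land, params,
                                        np.random.default_rng(3))
        # every selected species should be among the best-matching few
        g = land.latent[list(opt.columns)].to_numpy()
        o = opt.loc[list(table.species_ids)].to_numpy()
        for p in range(10):
            match = ((g[p][None, :] - o) ** 2).sum(axis=1)
            chosen = np.flatnonzero(table.incidence[p])
            best10 = set(np.argsort(match)[:10])
            assert sum(c in best10 for c in chosen) >= 4

    def test_dispersal_limitation_creates_distance_decay(self):
        params = SimulationParams(n_plots=20, n_species=120,
                                  target_richness=25, filter_strength=0.0,
                                  dispersal_scale=10.0)
        sd = generate_dataset(params, seed=9)
        dm = betadiv.dissimilarity_matrix(sd.dataset.community, "sorensen")
        from betascape.pcnm import geographic_distances
        gd = geographic_distances(sd.dataset.coordinates)
        iu = np.triu_indices(20, 1)
        rho = stats.spearmanr(gd.values[iu], dm.values[iu]).statistic
        assert rho > 0.3


class TestGenerateDataset:
    def test_seed_determinism(self):
        params = SimulationParams(n_plots=8, n_species=40, target_richness=10)
        a = generate_dataset(params, seed=42)
        b = generate_dataset(params, seed=42)
        assert (a.dataset.community.incidence ==
                b.dataset.community.incidence).all()
        assert a.dataset.phylogeny.newick() == b.dataset.phylogeny.newick()
        assert a.dataset.environment.variables.equals(
            b.dataset.environment.variables)
        assert np.allclose(a.dataset.coordinates.xy,
                           b.dataset.coordinates.xy)

    def test_ground_truth_aligned(self, small_synthetic):
        sd = small_synthetic
        assert list(sd.niche_optima.index) == \
            list(sd.dataset.phylogeny.tip_labels)
        assert set(sd.seed_sources.index) == set(sd.niche_optima.index)
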