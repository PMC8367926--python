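import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import oracles
from betascape.datasets import DissimilarityMatrix
from betascape.ordination import (adjusted_r2, db_rda, forward_select, nmds,
                                  pca, permutation_pseudo_f, rda)


def dmat(values, tag="euclidean"):
    ids = tuple(f"p{i+1}" for i in range(values.shape[0]))
    return DissimilarityMatrix(ids, values, tag)


class TestPCA:
    def test_perfectly_correlated_pair_one_axis(self):
        x = np.linspace(0, 1, 12)
        res = pca(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        res = pca(rng.normal(size=(20, 6)))
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_score_covariance_is_diagonal_eigenvalues(self):
        rng = np.random.default_rng(1)
        res = pca(rng.normal(size=(30, 4)), use_correlation=False)
        cov = np.cov(res.scores, rowvar=False)
        assert np.allclose(cov, np.diag(res.eigenvalues), atol=1e-10)

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="flat"):
            pca(pd.DataFrame({"flat": [1.0, 1.0, 1.0],
                              "ok": [1.0, 2.0, 3.0]}))


class TestNMDS:
    def test_recovers_true_configuration(self):
        rng = np.random.default_rng(2)
        truth = rng.normal(size=(15, 2))
        d = squareform(pdist(truth))
        res = nmds(dmat(d), k=2, n_starts=8, rng=0)
        assert res.stress < 0.01
        # Procrustes error to the truth
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(truth, res.scores)
        assert disparity < 1e-2

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(size=(15, 2))
        d = squareform(pdist(truth))
        res = nmds(dmat(np.sqrt(d)), k=2, n_starts=8, rng=0)
        assert res.stress < 0.01

    def test_full_dimension_embeds_exactly(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 4))
        d = squareform(pdist(pts))
        res = nmds(dmat(d), k=4, n_starts=10, rng=0)
        assert res.stress < 1e-3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nmds(dmat(np.zeros((4, 4))), k=2, n_starts=2, rng=0)


class TestRDA:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 3))
        y = x @ rng.normal(size=(3, 4))
        assert rda(y, x).r2 == pytest.approx(1.0)

    def test_orthogonal_predictors_zero_r2(self):
        n = 16
        y = np.zeros((n, 2))
        y[:, 0] = np.tile([1.0, -1.0], n // 2)
        y[:, 1] = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        x = np.arange(n, dtype=float)[:, None]
        x = x - x.mean()
        # construct y orthogonal to x
        y -= x @ np.linalg.lstsq(x, y, rcond=None)[0]
        assert rda(y, x).r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_per_column_ols_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            y = rng.normal(size=(25, 4))
            x = rng.normal(size=(25, 3))
            assert rda(y, x).r2 == pytest.approx(
                oracles.rda_r2_oracle(y, x), abs=1e-10)

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 2))
        x = np.hstack([x, x[:, :1] * 2.0])
        with pytest.raises(ValueError, match="rank"):
            rda(rng.normal(size=(15, 2)), x)

    def test_adjusted_below_r2(self):
        rng = np.random.default_rng(8)
        res = rda(rng.normal(size=(20, 3)), rng.normal(size=(20, 4)))
        assert res.adj_r2 < res.r2
        assert res.adj_r2 == pytest.approx(
            adjusted_r2(res.r2, 20, 4))


class TestDbRDA:
    def test_euclidean_equivalence(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            y = rng.normal(size=(18, 5))
            x = rng.normal(size=(18, 3))
            d = squareform(pdist(y))
            r_db = db_rda(dmat(d), x)
            r_direct = rda(y, x)
            assert r_db.r2 == pytest.approx(r_direct.r2, abs=1e-8)
            k = min(len(r_db.proportion_explained),
                    len(r_direct.proportion_explained))
            assert np.allclose(r_db.proportion_explained[:k],
                               r_direct.proportion_explained[:k], atol=1e-8)

    def test_pcoa_axes_as_predictors_saturate(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(12, 3))
        d = squareform(pdist(y))
        from betascape.ordination import pcoa_axes
        coords, _ = pcoa_axes(dmat(d))
        assert db_rda(dmat(d), coords[:, :3]).r2 > 0.8

    def test_group_separation_single_axis(self):
        # two groups of identical plots, zero within-group dissimilarity
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        x = np.array([0.0] * 3 + [1.0] * 3)[:, None]
        res = db_rda(dmat(d), x)
        assert res.r2 == pytest.approx(1.0)
        assert res.proportion_explained[0] == pytest.approx(res.r2)


class TestPermutationTest:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n_sim, rejections = 100, 0
        for s in range(n_sim):
            y = rng.normal(size=(15, 2))
            x = rng.normal(size=(15, 2))
            _, p = permutation_pseudo_f(y, x, n_perm=99, rng=s)
            rejections += p <= 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < band + 1e-9

    def test_perfect_dependence_minimum_p(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(12, 2))
        y = x @ np.array([[1.0, 0.0], [0.0, 2.0]])
        f, p = permutation_pseudo_f(y, x, n_perm=99, rng=0)
        assert p == pytest.approx(1 / 100)

    def test_predictor_column_order_irrelevant(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(14, 2))
        x = rng.normal(size=(14, 3))
        _, p1 = permutation_pseudo_f(y, x, n_perm=99, rng=5)
        _, p2 = permutation_pseudo_f(y, x[:, ::-1], n_perm=99, rng=5)
        assert p1 == p2

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=(14, 2))
        x = rng.normal(size=(14, 2))
        out1 = permutation_pseudo_f(y, x, n_perm=199, rng=7)
        out2 = permutation_pseudo_f(y, x, n_perm=199, rng=7)
        assert out1 == out2

    def test_partial_test_controls_condition(self):
        """Freedman-Lane: x tested given z has calibrated type-I error
        even when z strongly drives y."""
        rng = np.random.default_rng(15)
        n_sim, rejections = 60, 0
        for s in range(n_sim):
            z = rng.normal(size=(20, 1))
            y = z @ np.array([[2.0, 1.0]]) + rng.normal(size=(20, 2))
            x = rng.normal(size=(20, 1))
            _, p = permutation_pseudo_f(y, x, n_perm=99, rng=s, condition=z)
            rejections += p <= 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert rejections / n_sim < 0.05 + band


class TestForwardSelect:
    def test_strong_predictor_first_whenever_any_selected(self):
        """With one real predictor among noise, any non-empty selection
        must start with the real one.  (The adjusted-R^2 cap legitimately
        empties some runs: with a single true variable the one-variable
        adjusted R^2 sits at the all-variable cap in expectation, so the
        cap binds in roughly half the runs - vegan's ordiR2step behaves
        the same way.)"""
        rng = np.random.default_rng(16)
        nonempty = 0
        for s in range(20):
            x = rng.normal(size=(40, 10))
            y = x[:, [0]] + rng.normal(size=(40, 1))  # marginal R2 ~ 0.5
            trace = forward_select(
                y, pd.DataFrame(x, columns=[f"v{i}" for i in range(10)]),
                n_perm=99, rng=s)
            if trace.selected:
                nonempty += 1
                assert trace.selected[0] == "v0"
        assert nonempty >= 5

    def test_response_in_candidates_selected_with_min_p(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=(20, 1))
        cands = pd.DataFrame({"self": y[:, 0],
                              "noise": rng.normal(size=20)})
        trace = forward_select(y, cands, n_perm=99, rng=0)
        assert trace.selected[0] == "self"
        assert trace.steps[0].p == pytest.approx(1 / 100)

    def test_pure_noise_rarely_selects(self):
        rng = np.random.default_rng(18)
        n_sim, any_selected = 60, 0
        for s in range(n_sim):
            y = rng.normal(size=(30, 2))
            x = pd.DataFrame(rng.normal(size=(30, 8)))
            x.columns = [f"n{i}" for i in range(8)]
            trace = forward_select(y, x, n_perm=99, rng=s)
            any_selected += bool(trace.selected)
        band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert any_selected / n_sim < 0.05 + band

    def test_trace_respects_double_stopping(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(35, 6))
        y = x[:, :2] @ rng.normal(size=(2, 2)) + 0.3 * rng.normal(size=(35, 2))
        trace = forward_select(
            y, pd.DataFrame(x, columns=list("abcdef")), n_perm=99, rng=1)
        cum = [s.cum_adj_r2 for s in trace.steps]
        assert all(s.p <= 0.05 for s in trace.steps)
        assert all(np.diff(cum) >= -1e-12)
        assert all(c <= trace.global_adj_r2 + 1e-12 for c in cum)
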