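"""Stage 1: thresholds, two-level polychorics, pooled covariances."""

import numpy as np
import pytest

from mlfa import study
from mlfa.data import OrdinalDataset
from mlfa.icc import fit_item_probit
from mlfa.moments import (
    DegenerateItemError,
    PairwiseLikelihood,
    correlation_matrices,
    estimate_thresholds,
    nearest_psd_corr,
    pairwise_polychoric_twolevel,
    pooled_within_between_cov,
    summarize_correlations,
)
from mlfa.params import ClusterDesign
from mlfa.simulate import generate_dataset

from conftest import pair_params


class TestEstimateThresholds:
    def test_equal_category_weights_quantile_identity(self):
        resp = np.tile([1, 2, 3, 4], 25).reshape(-1, 1).astype(float)
        data = OrdinalDataset(responses=resp, cluster_id=np.arange(100) % 2,
                              n_categories=np.array([4]))
        t = estimate_thresholds(data, 0)
        assert np.allclose(t, [-0.6745, 0.0, 0.6745], atol=1e-4)

    def test_generator_round_trip(self):
        cuts = np.array([-1.0, 0.0, 0.5, 1.5])
        p = pair_params(0.0, 0.0, 1e-9, 1e-9, cuts1=cuts)
        data = generate_dataset(p, ClusterDesign(cluster_sizes=np.full(100, 1000)), 5)
        est = estimate_thresholds(data, 0)
        assert np.allclose(est, cuts, atol=0.02)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        resp = rng.integers(1, 5, size=(60, 1)).astype(float)
        base = OrdinalDataset(responses=resp, cluster_id=np.arange(60) % 3,
                              n_categories=np.array([4]))
        doubled = OrdinalDataset(responses=resp, cluster_id=np.arange(60) % 3,
                                 weight=np.full(60, 2.0), n_categories=np.array([4]))
        assert np.allclose(estimate_thresholds(base, 0),
                           estimate_thresholds(doubled, 0))

    def test_empty_category_names_the_category(self):
        resp = np.array([1, 1, 3, 3, 1, 3], dtype=float).reshape(-1, 1)
        data = OrdinalDataset(responses=resp, cluster_id=[0, 0, 0, 1, 1, 1],
                              n_categories=np.array([3]))
        with pytest.raises(DegenerateItemError, match="category 2"):
            estimate_thresholds(data, 0)


class TestPairwisePolychoric:
    def test_independent_items_near_zero(self):
        p = pair_params(0.0, 0.0, 0.15, 0.25)
        design = ClusterDesign(cluster_sizes=np.full(500, 100))
        rws, rbs = [], []
        for seed in range(3):
            data = generate_dataset(p, design, seed)
            fit = pairwise_polychoric_twolevel(data, 0, 1, n_nodes=5)
            rws.append(fit.r_W)
            rbs.append(fit.r_B)
        assert abs(np.median(rws)) < 0.05
        assert abs(np.median(rbs)) < 0.05

    def test_round_trip_recovery(self):
        p = pair_params(0.5, 0.8, 0.15, 0.25)
        design = ClusterDesign(cluster_sizes=np.full(500, 100))
        data = generate_dataset(p, design, seed=11)
        fit = pairwise_polychoric_twolevel(data, 0, 1, n_nodes=5)
        assert abs(fit.r_W - 0.5) < 0.03
        assert abs(fit.r_B - 0.8) < 0.08

    def test_ml_matches_grid_search(self):
        # 20-cluster toy; coarse-to-fine exhaustive search on the shared
        # likelihood must agree with the optimizer to the grid resolution
        p = pair_params(0.5, 0.8, 0.15, 0.25)
        design = ClusterDesign(cluster_sizes=np.full(20, 8))
        data = generate_dataset(p, design, seed=4)
        s1 = [fit_item_probit(data, j, n_nodes=7) for j in range(2)]
        fit = pairwise_polychoric_twolevel(data, 0, 1, stage1=s1, n_nodes=7)
        lik = PairwiseLikelihood(data, 0, 1, s1[0], s1[1], n_nodes=7)
        coarse = np.arange(-0.9, 0.91, 0.05)
        _, rw0, rb0 = max((lik.loglik(rw, rb), rw, rb)
                          for rw in coarse for rb in coarse)
        fine_w = np.arange(rw0 - 0.05, rw0 + 0.051, 0.01)
        fine_b = np.clip(np.arange(rb0 - 0.05, rb0 + 0.051, 0.01), -0.99, 0.99)
        ll, rw, rb = max((lik.loglik(a, b), a, b) for a in fine_w for b in fine_b)
        assert abs(fit.r_W - rw) <= 0.011
        assert abs(fit.r_B - rb) <= 0.011
        assert fit.loglik >= ll - 1e-6

    def test_optimum_beats_null(self):
        p = pair_params(0.4, 0.5, 0.1, 0.2)
        design = ClusterDesign(cluster_sizes=np.full(30, 10))
        data = generate_dataset(p, design, seed=2)
        s1 = [fit_item_probit(data, j, n_nodes=7) for j in range(2)]
        fit = pairwise_polychoric_twolevel(data, 0, 1, stage1=s1, n_nodes=7)
        lik = PairwiseLikelihood(data, 0, 1, s1[0], s1[1], n_nodes=7)
        assert fit.loglik >= lik.loglik(0.0, 0.0)

    def test_item_pair_order_symmetry(self):
        p = pair_params(0.4, 0.3, 0.1, 0.2)
        design = ClusterDesign(cluster_sizes=np.full(30, 10))
        data = generate_dataset(p, design, seed=9)
        s1 = [fit_item_probit(data, j, n_nodes=7) for j in range(2)]
        # stage1 given as the per-item list; the pair order must not matter
        f_ab = pairwise_polychoric_twolevel(data, 0, 1, stage1=s1, n_nodes=7)
        f_ba = pairwise_polychoric_twolevel(data, 1, 0, stage1=s1, n_nodes=7)
        assert np.isclose(f_ab.r_W, f_ba.r_W, atol=1e-3)
        assert np.isclose(f_ab.r_B, f_ba.r_B, atol=1e-3)

    def test_weight_scale_invariance(self):
        p = pair_params(0.4, 0.3, 0.1, 0.2)
        design = ClusterDesign(cluster_sizes=np.full(20, 10))
        data = generate_dataset(p, design, seed=5)
        scaled = OrdinalDataset(responses=data.responses, cluster_id=data.cluster_id,
                                weight=np.full(data.n_obs, 3.0),
                                n_categories=data.n_categories)
        f1 = pairwise_polychoric_twolevel(data, 0, 1, n_nodes=7)
        f2 = pairwise_polychoric_twolevel(scaled, 0, 1, n_nodes=7)
        assert np.isclose(f1.r_W, f2.r_W, atol=1e-6)
        assert np.isclose(f1.r_B, f2.r_B, atol=1e-6)

    def test_cluster_constant_item_rejected(self):
        resp = np.column_stack([
            np.repeat([1.0, 3.0], 10),                 # constant within cluster
            np.tile([1, 2, 3, 2, 1], 4).astype(float),
        ])
        data = OrdinalDataset(responses=resp, cluster_id=np.repeat([0, 1], 10),
                              n_categories=np.array([3, 3]))
        s1 = [fit_item_probit(data, j, n_nodes=7) for j in range(2)]
        with pytest.raises(DegenerateItemError, match="within-cluster variation"):
            PairwiseLikelihood(data, 0, 1, s1[0], s1[1], n_nodes=7)


class TestCorrelationMatrices:
    def test_between_exceeds_within_as_in_study(self, study_sims):
        hits = 0
        for sim in study_sims:
            mw = summarize_correlations(sim["moments"].R_W)[0]
            mb = summarize_correlations(sim["moments"].R_B)[0]
            hits += int(mb > mw)
        assert hits >= int(0.9 * len(study_sims))

    def test_round_trip_recovery(self, study_sims, study_config):
        from mlfa.params import implied_moments
        params, _ = study_config
        SW, SB = implied_moments(params)
        dB = np.sqrt(np.diag(SB))
        RB = SB / np.outer(dB, dB)
        RW = SW.copy()
        np.fill_diagonal(RW, 1.0)
        tri = np.tril_indices(10, -1)
        errW = np.mean([np.abs(s["moments"].R_W - RW)[tri].mean() for s in study_sims])
        errB = np.mean([np.abs(s["moments"].R_B - RB)[tri].mean() for s in study_sims])
        assert errW < 0.03
        assert errB < 0.10

    def test_pair_n_ledger(self, tiny_dataset):
        mom = correlation_matrices(tiny_dataset, n_nodes=5)
        obs = ~np.isnan(tiny_dataset.responses)
        for a in range(3):
            for b in range(a + 1, 3):
                assert mom.pair_n[a, b] == int(np.sum(obs[:, a] & obs[:, b]))
            assert mom.pair_n[a, a] == int(obs[:, a].sum())


class TestPooledCov:
    def test_hand_computed_balanced_toy(self):
        y = np.array([0.0, 2.0, 4.0, 6.0])
        S_PW, S_B, c = pooled_within_between_cov(y, [0, 0, 1, 1])
        assert np.isclose(S_PW[0, 0], 2.0)
        assert np.isclose(S_B[0, 0], 16.0)
        assert np.isclose(c, 2.0)
        assert np.isclose((S_B[0, 0] - S_PW[0, 0]) / c, 7.0)

    def test_one_observation_per_cluster_errors(self):
        with pytest.raises(ValueError, match="one observation per cluster"):
            pooled_within_between_cov(np.array([1.0, 2.0, 3.0]), [0, 1, 2])

    def test_expectation_identities_by_simulation(self):
        rng = np.random.default_rng(12)
        J, nj = 1000, 20
        Sigma_B = np.array([[0.3, 0.1], [0.1, 0.2]])
        Sigma_W = np.array([[1.0, 0.4], [0.4, 1.5]])
        u = rng.multivariate_normal(np.zeros(2), Sigma_B, size=J)
        e = rng.multivariate_normal(np.zeros(2), Sigma_W, size=J * nj)
        y = np.repeat(u, nj, axis=0) + e
        S_PW, S_B, c = pooled_within_between_cov(y, np.repeat(np.arange(J), nj))
        assert np.allclose(S_PW, Sigma_W, rtol=0.05, atol=0.02)
        assert np.allclose((S_B - S_PW) / c, Sigma_B, rtol=0.05, atol=0.03)


class TestSummaries:
    def test_published_within_matrix_aggregates(self):
        assert summarize_correlations(study.CORR_WITHIN) == (0.304, 0.093, 0.557)

    def test_published_between_matrix_aggregates(self):
        assert summarize_correlations(study.CORR_BETWEEN) == (0.685, 0.205, 0.934)

    def test_identity_matrix(self):
        assert summarize_correlations(np.eye(4)) == (0.0, 0.0, 0.0)

    def test_bad_input_errors(self):
        with pytest.raises(ValueError):
            summarize_correlations(np.eye(1))
        with pytest.raises(ValueError):
            summarize_correlations(np.array([[1.0, 0.5], [0.1, 1.0]]))


def test_nearest_psd_repair():
    R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    rep, changed = nearest_psd_corr(R)
    assert changed
    assert np.linalg.eigvalsh(rep).min() >= 0
    assert np.allclose(np.diag(rep), 1.0)
    ok, changed2 = nearest_psd_corr(np.eye(3))
    assert not changed2
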