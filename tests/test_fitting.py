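"""Stage-2 fitting: recovery, indices, residuals, model comparison."""

import numpy as np
import pytest

from mlfa.fitting import (
    baseline_discrepancy,
    communality_from_loadings,
    compare_models,
    fit_indices,
    fit_mlfa,
    residual_matrices,
)
from mlfa.model import ModelSpec, count_df
from mlfa.moments import TwoLevelMoments
from mlfa.params import TwoLevelFactorParams, implied_moments


def _simple_structure_params(seed=0):
    """Generative params with exact simple structure at both levels."""
    rng = np.random.default_rng(seed)
    M = 10
    lam_W = np.zeros((M, 2))
    lam_W[:7, 0] = rng.uniform(0.4, 0.8, 7)
    lam_W[7:, 1] = rng.uniform(0.5, 0.8, 3)
    psi_W = np.array([[1.0, 0.5], [0.5, 1.0]])
    h2 = np.einsum("ik,kl,il->i", lam_W, psi_W, lam_W)
    var_B = rng.uniform(0.08, 0.3, M)
    lam_B_std = rng.uniform(0.5, 0.95, M)
    lam_B = (lam_B_std * np.sqrt(var_B)).reshape(-1, 1)
    return TwoLevelFactorParams(
        lambda_W=lam_W, lambda_B=lam_B, psi_W=psi_W, psi_B=[[1.0]],
        theta_W=1 - h2, theta_B=var_B * (1 - lam_B_std**2),
        thresholds=[np.array([-1.0, 0.0, 1.0])] * M)


def moments_from_params(params, n_obs=2000, n_clusters=65):
    SW, SB = implied_moments(params)
    dB = np.sqrt(np.diag(SB))
    R_W = SW.copy()
    np.fill_diagonal(R_W, 1.0)
    M = params.n_items
    return TwoLevelMoments(
        thresholds=[t for t in params.thresholds],
        thresholds_model=[t for t in params.thresholds],
        R_W=R_W, R_B=SB / np.outer(dB, dB), var_B=np.diag(SB),
        pair_n=np.full((M, M), n_obs), n_obs=n_obs, n_clusters=n_clusters,
        item_labels=[f"item_{j+1}" for j in range(M)],
        n_categories=np.full(M, len(params.thresholds[0]) + 1))


@pytest.fixture(scope="module")
def exact_moments():
    params = _simple_structure_params()
    return params, moments_from_params(params)


class TestZeroNoiseRecovery:
    def test_cfa_recovers_generative_parameters(self, exact_moments, cfa_patterns):
        params, mom = exact_moments
        fit = fit_mlfa(mom, ModelSpec.cfa(*cfa_patterns))
        assert fit.discrepancy < 1e-8
        pat_W = cfa_patterns[0]
        assert np.abs(fit.lambda_W_hat[pat_W] - params.lambda_W[pat_W]).max() < 1e-4
        assert abs(fit.psi_W_hat[0, 1] - 0.5) < 1e-4
        dB = np.sqrt(np.diag(implied_moments(params)[1]))
        assert np.abs(np.abs(fit.lambda_B_std[:, 0])
                      - params.lambda_B[:, 0] / dB).max() < 1e-4

    def test_efa_reaches_zero_discrepancy(self, exact_moments):
        _, mom = exact_moments
        fit = fit_mlfa(mom, ModelSpec.efa(2, 1))
        assert fit.discrepancy < 1e-10
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0
        assert fit.srmr_W < 1e-5 and fit.srmr_B < 1e-5

    def test_df_matches_ledger(self, exact_moments, cfa_patterns):
        _, mom = exact_moments
        for spec in (ModelSpec.efa(2, 1), ModelSpec.cfa(*cfa_patterns),
                     ModelSpec.hlvm(cfa_patterns[0])):
            fit = fit_mlfa(mom, spec)
            assert fit.df == count_df(spec, 10, mom.n_categories)
            stats = int(np.sum(mom.n_categories - 1)) + 45 + 55
            assert fit.df == stats - sum(fit.ledger.values())


class TestRotationInvariance:
    def test_indices_unchanged_by_rotation(self, exact_moments):
        params = _simple_structure_params(seed=3)
        mom = moments_from_params(params)
        # add a little structured perturbation so the fit is imperfect
        mom.R_W[0, 1] = mom.R_W[1, 0] = mom.R_W[0, 1] + 0.05
        raw = fit_mlfa(mom, ModelSpec.efa(2, 1), rotate=False)
        rot = fit_mlfa(mom, ModelSpec.efa(2, 1), rotate=True)
        for attr in ("discrepancy", "chi2", "cfi", "rmsea", "srmr_W", "srmr_B"):
            assert np.isclose(getattr(raw, attr), getattr(rot, attr), atol=1e-9)
        # rotation only re-expresses the within solution
        SW_raw = raw.lambda_W_hat @ raw.psi_W_hat @ raw.lambda_W_hat.T
        SW_rot = rot.lambda_W_hat @ rot.psi_W_hat @ rot.lambda_W_hat.T
        assert np.allclose(SW_raw, SW_rot, atol=1e-6)


class TestFitIndices:
    def test_perfect_fit_limits(self):
        R = np.eye(3)
        chi2, p, cfi, rmsea, sW, sB = fit_indices(
            0.0, 5, 1.0, 8, 100, R, R, R, R)
        assert (chi2, p, cfi, rmsea, sW, sB) == (0.0, 1.0, 1.0, 0.0, 0.0, 0.0)

    def test_chi2_below_df_clamps_rmsea(self):
        R = np.eye(3)
        out = fit_indices(0.001, 5, 1.0, 8, 100, R, R, R, R)
        rmsea = out[3]
        assert rmsea == 0.0

    def test_srmr_hand_computation(self):
        # uniform 0.1 off-diagonal residuals on three items -> SRMR 0.1
        S = np.eye(3)
        R = S + 0.1 * (np.ones((3, 3)) - np.eye(3))
        *_, sW, sB = fit_indices(0.1, 2, 1.0, 3, 50, R, S, R, S)
        assert np.isclose(sW, 0.1)
        assert np.isclose(sB, 0.1)

    def test_zero_df_reports_rmsea_not_applicable(self):
        R = np.eye(3)
        chi2, p, cfi, rmsea, *_ = fit_indices(0.0, 0, 1.0, 3, 100, R, R, R, R)
        assert np.isnan(rmsea)


class TestCommunalities:
    def test_published_worked_example(self):
        # item 'willing to help': loadings (0.735, 0.038), factor corr 0.521
        h2 = communality_from_loadings([0.735, 0.038], [[1, 0.521], [0.521, 1]])
        assert round(float(h2[0]) * 100, 1) == 57.1

    def test_single_factor_square(self):
        h2 = communality_from_loadings(np.array([[0.972]]))
        assert np.isclose(h2[0], 0.9448, atol=1e-4)

    def test_zero_loadings(self):
        assert np.allclose(communality_from_loadings(np.zeros((4, 2))), 0.0)

    def test_fit_reports_generative_communalities(self, exact_moments, cfa_patterns):
        params, mom = exact_moments
        fit = fit_mlfa(mom, ModelSpec.cfa(*cfa_patterns))
        h2_true = np.einsum("ik,kl,il->i", params.lambda_W, params.psi_W, params.lambda_W)
        assert np.allclose(fit.communality_W, h2_true, atol=1e-4)
        assert np.all(fit.communality_B <= 1 + 1e-9)


class TestResidualsAndComparison:
    def test_saturated_fit_zero_residuals(self, exact_moments, cfa_patterns):
        _, mom = exact_moments
        fit = fit_mlfa(mom, ModelSpec.cfa(*cfa_patterns))
        res_W, res_B = residual_matrices(fit, mom)
        assert np.abs(res_W).max() < 1e-6
        assert np.abs(res_B).max() < 1e-5

    def test_hlvm_misfit_concentrates_between(self, study_sims):
        hits_resid = 0
        hits_cfi = 0
        for sim in study_sims:
            res_W, res_B = residual_matrices(sim["hlvm"], sim["moments"])
            tri = np.tril_indices_from(res_W, k=-1)
            hits_resid += int(np.abs(res_B[tri]).max() > np.abs(res_W[tri]).max())
            hits_cfi += int(sim["hlvm"].cfi < sim["cfa"].cfi)
        n = len(study_sims)
        assert hits_resid >= int(0.9 * n)
        assert hits_cfi >= int(0.9 * n)

    def test_dropping_between_loading_inflates_that_row(self, exact_moments):
        params, mom = exact_moments
        pat_W = np.zeros((10, 2), dtype=bool)
        pat_W[:7, 0] = True
        pat_W[7:, 1] = True
        pat_B = np.ones((10, 1), dtype=bool)
        pat_B_drop = pat_B.copy()
        pat_B_drop[4, 0] = False
        full = fit_mlfa(mom, ModelSpec.cfa(pat_W, pat_B))
        drop = fit_mlfa(mom, ModelSpec.cfa(pat_W, pat_B_drop))
        _, res_full = residual_matrices(full, mom)
        _, res_drop = residual_matrices(drop, mom)
        row = np.abs(res_drop[4]).sum()
        others = np.abs(res_drop[np.arange(10) != 4]).sum()
        assert row > np.abs(res_full[4]).sum() + 0.1
        assert row > others / 9

    def test_nested_monotonicity_and_deltas(self, exact_moments, cfa_patterns):
        _, mom = exact_moments
        cfa = fit_mlfa(mom, ModelSpec.cfa(*cfa_patterns))
        hlvm = fit_mlfa(mom, ModelSpec.hlvm(cfa_patterns[0]))
        rep = compare_models(cfa, hlvm)
        assert rep["nested"]
        assert rep["delta_discrepancy"] >= 0
        assert rep["delta_df"] == 17

    def test_identical_specs_zero_deltas(self, exact_moments, cfa_patterns):
        _, mom = exact_moments
        a = fit_mlfa(mom, ModelSpec.cfa(*cfa_patterns))
        b = fit_mlfa(mom, ModelSpec.cfa(*cfa_patterns))
        rep = compare_models(a, b)
        assert abs(rep["delta_discrepancy"]) < 1e-10
        assert rep["delta_df"] == 0

    def test_hlvm_on_study_data_never_beats_cfa(self, study_sims):
        for sim in study_sims:
            assert sim["hlvm"].discrepancy >= sim["cfa"].discrepancy - 1e-8


def test_baseline_discrepancy_counts():
    params = _simple_structure_params()
    mom = moments_from_params(params)
    F, df = baseline_discrepancy(mom)
    assert F > 0
    assert df == 140 - 40 - 10
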