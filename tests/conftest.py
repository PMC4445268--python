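"""Shared fixtures.

``study_sims`` is the expensive one: twenty study-scale simulated datasets
run through stage 1 and the stage-2 model battery once per session, shared
by the recovery, selection, and model-comparison tests.
"""

import numpy as np
import pytest

from mlfa.data import OrdinalDataset
from mlfa.fitting import fit_mlfa
from mlfa.model import ModelSpec
from mlfa.moments import correlation_matrices
from mlfa.params import ClusterDesign, TwoLevelFactorParams
from mlfa.pipeline import PipelineConfig, select_efa_model
from mlfa.simulate import default_study_config, generate_dataset

N_STUDY_SEEDS = 20
N_NODES_SIM = 5   # adaptive quadrature; see docs/methods.md on node counts


def single_item_params(tau2, cuts, lam_W=0.0):
    """One-item two-level params with the given between variance."""
    lam_W = np.atleast_2d(lam_W)
    return TwoLevelFactorParams(
        lambda_W=lam_W, lambda_B=np.zeros((1, 1)),
        psi_W=[[1.0]], psi_B=[[1.0]],
        theta_W=np.array([1.0 - float(lam_W[0, 0]) ** 2]),
        theta_B=np.array([tau2]),
        thresholds=[np.asarray(cuts, dtype=float)],
    )


def pair_params(r_W, r_B, v1, v2, cuts1=(-1.0, 0.0, 0.5, 1.5), cuts2=(-1.2, -0.3, 0.6, 1.3)):
    """Two-item params with given within/between correlations and between
    variances (within-standardized scale)."""
    sign = np.sign(r_W) if r_W != 0 else 1.0
    lam_W = np.array([[np.sqrt(abs(r_W))], [sign * np.sqrt(abs(r_W))]])
    sb = np.sign(r_B) if r_B != 0 else 1.0
    lam_B = np.array([[np.sqrt(abs(r_B) * v1)], [sb * np.sqrt(abs(r_B) * v2)]])
    return TwoLevelFactorParams(
        lambda_W=lam_W, lambda_B=lam_B, psi_W=[[1.0]], psi_B=[[1.0]],
        theta_W=1.0 - lam_W[:, 0] ** 2,
        theta_B=np.array([v1 * (1 - abs(r_B)), v2 * (1 - abs(r_B))]),
        thresholds=[np.asarray(cuts1, float) * np.sqrt(1 + v1),
                    np.asarray(cuts2, float) * np.sqrt(1 + v2)],
    )


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()


@pytest.fixture(scope="session")
def cfa_patterns():
    pat_W = np.zeros((10, 2), dtype=bool)
    pat_W[:7, 0] = True
    pat_W[7:, 1] = True
    pat_B = np.ones((10, 1), dtype=bool)
    return pat_W, pat_B


@pytest.fixture(scope="session")
def study_sims(study_config, cfa_patterns):
    """Stage-1 moments plus CFA/HLVM fits and EFA-grid selection for
    N_STUDY_SEEDS study-scale simulated datasets."""
    params, design = study_config
    pat_W, pat_B = cfa_patterns
    cfg = PipelineConfig(simulate=True, n_nodes=N_NODES_SIM)
    out = []
    for seed in range(N_STUDY_SEEDS):
        data = generate_dataset(params, design, seed)
        moments = correlation_matrices(data, n_nodes=N_NODES_SIM)
        cfa = fit_mlfa(moments, ModelSpec.cfa(pat_W, pat_B), N=data.n_obs)
        hlvm = fit_mlfa(moments, ModelSpec.hlvm(pat_W), N=data.n_obs)
        _, grid = select_efa_model(moments, cfg, n_obs=data.n_obs)
        out.append({
            "seed": seed, "data": data, "moments": moments,
            "cfa": cfa, "hlvm": hlvm,
            "selected": grid.attrs["selected"],
        })
    return out


@pytest.fixture
def tiny_dataset():
    """Ten observations, two clusters, three items with a known missing
    pattern (for read/write and pairwise-present ledger checks)."""
    resp = np.array([
        [1, 2, 3],
        [2, np.nan, 1],
        [3, 1, 2],
        [1, 1, np.nan],
        [2, 3, 3],
        [np.nan, 2, 2],
        [3, 3, 1],
        [2, 1, 2],
        [1, 2, np.nan],
        [3, 3, 3],
    ], dtype=float)
    return OrdinalDataset(
        responses=resp,
        cluster_id=np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1]),
        n_categories=np.array([3, 3, 3]),
    )
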