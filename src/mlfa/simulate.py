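"""Synthetic clustered ordinal data under the two-level ordinal factor model.

The generator draws the latent pieces exactly as the model states them:
cluster-level factors ``eta_B`` and residuals ``zeta`` first (cluster-major),
then individual-level factors ``eta_W`` and residuals ``eps`` row-major, forms
the continuous latent responses

    y*_ij = gamma + Lambda_W eta_Wij + Lambda_B eta_Bj + zeta_j + eps_ij

and cuts each item at its thresholds.  One seeded ``numpy`` generator per
call; the draw order above is part of the contract so a fixed seed gives a
byte-identical dataset.

:func:`default_study_config` parameterizes the generator to emulate the
collective-efficacy survey this package was built around: 65 clusters,
2,594 respondents, 10 five-category items, two correlated within-level
factors (social cohesion, items 1-7; informal social control, items 8-10),
one between-level factor, and item ICCs spanning roughly 0.06-0.26.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import study
from .data import OrdinalDataset
from .params import ClusterDesign, TwoLevelFactorParams, implied_moments, implied_icc

__all__ = [
    "LatentRealization",
    "generate_dataset",
    "generate_latent",
    "default_study_config",
    "add_missingness",
]


@dataclass
class LatentRealization:
    """All latent draws behind one simulated dataset."""

    eta_B: np.ndarray    # (J, p_B) cluster factor scores
    zeta: np.ndarray     # (J, M) cluster residuals
    nu: np.ndarray       # (J, M) cluster intercepts gamma + Lambda_B eta_B + zeta
    eta_W: np.ndarray    # (N, p_W) individual factor scores
    epsilon: np.ndarray  # (N, M) individual residuals
    ystar: np.ndarray    # (N, M) continuous latent responses
    mu: np.ndarray       # (N, M) expected values nu[cluster] + Lambda_W eta_W
    cluster_of_row: np.ndarray  # (N,) cluster index per row


def _chol_psd(psi):
    # tolerate PSD-but-singular factor covariances
    w, v = np.linalg.eigh(psi)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def generate_latent(params: TwoLevelFactorParams, design: ClusterDesign, seed: int) -> LatentRealization:
    """Draw the latent two-level realization (no categorization)."""
    rng = np.random.default_rng(seed)
    J = design.n_clusters
    N = design.n_obs
    M = params.n_items
    p_W = params.lambda_W.shape[1]
    p_B = params.lambda_B.shape[1]

    # cluster-level draws first (cluster-major)
    eta_B = rng.standard_normal((J, p_B)) @ _chol_psd(params.psi_B).T
    zeta = rng.standard_normal((J, M)) * np.sqrt(params.theta_B)
    nu = params.gamma + eta_B @ params.lambda_B.T + zeta

    # then individual-level draws (row-major; rows are cluster-major)
    eta_W = rng.standard_normal((N, p_W)) @ _chol_psd(params.psi_W).T
    epsilon = rng.standard_normal((N, M)) * np.sqrt(params.theta_W)

    cluster_of_row = np.repeat(np.arange(J), design.cluster_sizes)
    mu = nu[cluster_of_row] + eta_W @ params.lambda_W.T
    ystar = mu + epsilon
    return LatentRealization(eta_B, zeta, nu, eta_W, epsilon, ystar, mu, cluster_of_row)


def categorize(ystar: np.ndarray, thresholds) -> np.ndarray:
    """Cut continuous responses into codes ``1..K`` at ascending thresholds."""
    out = np.empty_like(ystar)
    for j, t in enumerate(thresholds):
        t = np.asarray(t, dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"thresholds of item {j + 1} are not strictly ascending")
        out[:, j] = np.searchsorted(t, ystar[:, j]) + 1
    return out


def generate_dataset(params: TwoLevelFactorParams, design: ClusterDesign, seed: int) -> OrdinalDataset:
    """Simulate one clustered ordinal dataset.

    Reproducible: identical ``(params, design, seed)`` give a byte-identical
    dataset.
    """
    for j, t in enumerate(params.thresholds):
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"thresholds of item {j + 1} are not strictly ascending")
    lat = generate_latent(params, design, seed)
    codes = categorize(lat.ystar, params.thresholds)
    return OrdinalDataset(
        responses=codes,
        cluster_id=lat.cluster_of_row,
        weight=design.weights.copy(),
        item_labels=[f"item_{j + 1}" for j in range(params.n_items)],
        n_categories=params.n_categories,
    )


def add_missingness(data: OrdinalDataset, rate: float, seed: int) -> OrdinalDataset:
    """Blank out cells completely at random with the given probability."""
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    resp = data.responses.copy()
    mask = rng.random(resp.shape) < rate
    resp[mask] = np.nan
    return OrdinalDataset(resp, data.cluster_id.copy(), data.weight.copy(),
                          list(data.item_labels), data.n_categories.copy())


# Cumulative category proportions used for the default thresholds.  The raw
# survey's category frequencies were never published; these are mildly
# left-skewed five-point agreement distributions, varied a little across
# items so no two items share cutpoints exactly.
_BASE_CUMPROBS = np.array([0.12, 0.40, 0.65, 0.88])


def default_study_config():
    """Generator configuration emulating the collective-efficacy survey.

    Returns
    -------
    params : TwoLevelFactorParams
        Within loadings, within factor correlation (0.521) and standardized
        between loadings set to the published rotated EFA solution; between
        variances set so the implied latent-response ICCs equal the published
        per-item ICCs (0.062-0.262).
    design : ClusterDesign
        65 clusters totalling 2,594 respondents; sizes near-equal (40 or 39,
        remainder assigned to the leading clusters), unit weights.
    """
    lam_W = study.EFA_LOADINGS_WITHIN.copy()
    phi = study.EFA_FACTOR_CORR_WITHIN
    psi_W = np.array([[1.0, phi], [phi, 1.0]])
    h2_W = np.einsum("ik,kl,il->i", lam_W, psi_W, lam_W)
    theta_W = 1.0 - h2_W  # delta convention: unit within-level total variance

    icc = study.ICC_TABLE[:, 0]
    var_B = icc / (1.0 - icc)
    lam_B_std = study.EFA_LOADINGS_BETWEEN[:, 0]
    lam_B = (lam_B_std * np.sqrt(var_B)).reshape(-1, 1)
    theta_B = var_B * (1.0 - lam_B_std**2)
    psi_B = np.array([[1.0]])

    # thresholds on the total latent-response scale (variance 1 + var_B)
    total_sd = np.sqrt(1.0 + var_B)
    thresholds = []
    for m in range(10):
        shift = 0.03 * ((m % 3) - 1)  # small deterministic per-item variety
        cum = np.clip(_BASE_CUMPROBS + shift, 0.02, 0.98)
        thresholds.append(norm.ppf(cum) * total_sd[m])

    params = TwoLevelFactorParams(
        lambda_W=lam_W, lambda_B=lam_B, psi_W=psi_W, psi_B=psi_B,
        theta_W=theta_W, theta_B=theta_B, thresholds=thresholds,
    )

    n_total, J = 2594, 65
    base = n_total // J
    sizes = np.full(J, base)
    sizes[: n_total - base * J] += 1
    design = ClusterDesign(cluster_sizes=sizes)
    return params, design
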