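"""Generative parameterization of the two-level ordinal factor model.

The latent response ``y*`` of respondent ``i`` in cluster ``j`` decomposes as

    y*_ij = gamma + Lambda_W eta_Wij + Lambda_B eta_Bj + zeta_j + eps_ij

with independent normal factors and residuals at each level.  Observed
ordinal codes arise by cutting ``y*`` at per-item thresholds (ordinal probit
link).  The within-level total variance is standardized to 1 per item (delta
convention), so thresholds are standard-normal cutpoints up to the between
variance inflation and the item intraclass correlation is
``Sigma_B[m,m] / (Sigma_B[m,m] + 1)`` on the latent-response scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TwoLevelFactorParams",
    "ClusterDesign",
    "implied_moments",
    "implied_icc",
]


def _as_psd(mat, name):
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be a symmetric square matrix")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {w.min():.3g})")
    return mat


@dataclass
class TwoLevelFactorParams:
    """Full parameter set of the two-level ordinal factor model.

    Attributes
    ----------
    gamma : (M,) overall latent-response means (0 under the delta convention).
    lambda_W, lambda_B : (M, p_W), (M, p_B) loading matrices.
    psi_W, psi_B : factor covariance matrices, symmetric PSD.
    theta_W, theta_B : (M,) within / between residual variances.
    thresholds : list of (K_m - 1,) strictly ascending cutpoints per item.
    """

    lambda_W: np.ndarray
    lambda_B: np.ndarray
    psi_W: np.ndarray
    psi_B: np.ndarray
    theta_W: np.ndarray
    theta_B: np.ndarray
    thresholds: list
    gamma: np.ndarray = None

    def __post_init__(self):
        self.lambda_W = np.atleast_2d(np.asarray(self.lambda_W, dtype=float))
        self.lambda_B = np.atleast_2d(np.asarray(self.lambda_B, dtype=float))
        if self.lambda_W.shape[0] != self.lambda_B.shape[0]:
            raise ValueError("lambda_W and lambda_B must have the same number of items")
        m = self.lambda_W.shape[0]
        self.psi_W = _as_psd(self.psi_W, "psi_W")
        self.psi_B = _as_psd(self.psi_B, "psi_B")
        if self.psi_W.shape[0] != self.lambda_W.shape[1]:
            raise ValueError("psi_W dimension does not match lambda_W columns")
        if self.psi_B.shape[0] != self.lambda_B.shape[1]:
            raise ValueError("psi_B dimension does not match lambda_B columns")
        self.theta_W = np.asarray(self.theta_W, dtype=float)
        self.theta_B = np.asarray(self.theta_B, dtype=float)
        if self.theta_W.shape != (m,) or self.theta_B.shape != (m,):
            raise ValueError("theta_W / theta_B must be length-M vectors")
        if np.any(self.theta_W < 0) or np.any(self.theta_B < 0):
            raise ValueError("residual variances must be nonnegative")
        if self.gamma is None:
            self.gamma = np.zeros(m)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        if len(self.thresholds) != m:
            raise ValueError("one threshold vector required per item")
        for j, t in enumerate(self.thresholds):
            if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
                raise ValueError(f"thresholds of item {j + 1} must be strictly ascending")
        sw = np.einsum("ik,kl,il->i", self.lambda_W, self.psi_W, self.lambda_W) + self.theta_W
        if np.any(sw <= 0):
            raise ValueError("implied within variance must be strictly positive for every item")

    @property
    def n_items(self) -> int:
        return self.lambda_W.shape[0]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([len(t) + 1 for t in self.thresholds])

    def to_yaml(self, path) -> None:
        payload = {
            "gamma": self.gamma.tolist(),
            "lambda_W": self.lambda_W.tolist(),
            "lambda_B": self.lambda_B.tolist(),
            "psi_W": self.psi_W.tolist(),
            "psi_B": self.psi_B.tolist(),
            "theta_W": self.theta_W.tolist(),
            "theta_B": self.theta_B.tolist(),
            "thresholds": [t.tolist() for t in self.thresholds],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "TwoLevelFactorParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class ClusterDesign:
    """Cluster layout: number of clusters and per-cluster sample sizes."""

    cluster_sizes: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self):
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        if self.cluster_sizes.ndim != 1 or len(self.cluster_sizes) < 2:
            raise ValueError("at least 2 clusters required")
        if np.any(self.cluster_sizes < 1):
            raise ValueError("every cluster size must be >= 1")
        if self.weights is None:
            self.weights = np.ones(int(self.cluster_sizes.sum()))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if self.weights.shape != (int(self.cluster_sizes.sum()),):
            raise ValueError("weights must have one entry per observation")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_obs(self) -> int:
        return int(self.cluster_sizes.sum())


def implied_moments(params: TwoLevelFactorParams):
    """Model-implied within and between latent-response covariance matrices.

    Returns
    -------
    Sigma_W : (M, M) ``Lambda_W Psi_W Lambda_W' + diag(theta_W)``
    Sigma_B : (M, M) ``Lambda_B Psi_B Lambda_B' + diag(theta_B)``

    Their sum is the total latent-response covariance.
    """
    Sigma_W = params.lambda_W @ params.psi_W @ params.lambda_W.T + np.diag(params.theta_W)
    Sigma_B = params.lambda_B @ params.psi_B @ params.lambda_B.T + np.diag(params.theta_B)
    return Sigma_W, Sigma_B


def implied_icc(params: TwoLevelFactorParams, item: int) -> float:
    """Latent-response intraclass correlation of one item.

    Proportion of the item's latent-response variance lying between
    clusters: ``Sigma_B[m,m] / (Sigma_B[m,m] + Sigma_W[m,m])``.
    """
    Sigma_W, Sigma_B = implied_moments(params)
    tot = Sigma_B[item, item] + Sigma_W[item, item]
    if tot <= 0:
        raise ValueError("item has zero total latent-response variance")
    return float(Sigma_B[item, item] / tot)
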