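"""Scikit-learn style estimators over the two-level machinery.

Each estimator takes the item-response matrix ``X`` (codes ``1..K``, NaN for
missing) with the cluster labels passed as ``groups`` and optional
``sample_weight``, follows the ``fit`` / fitted-attribute (trailing
underscore) convention, and composes with sklearn tooling through
``get_params`` / ``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import OrdinalDataset
from .fitting import fit_mlfa
from .icc import fit_item_probit, icc_linear
from .model import ModelSpec
from .moments import correlation_matrices

__all__ = [
    "RandomInterceptOrdinalProbit",
    "TwoLevelPolychoric",
    "MultilevelFactorAnalysis",
]


def _build_dataset(X, groups, sample_weight):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d (observations x items)")
    if groups is None:
        raise ValueError("groups (cluster labels) are required")
    return OrdinalDataset(responses=X, cluster_id=np.asarray(groups),
                          weight=sample_weight)


class RandomInterceptOrdinalProbit(BaseEstimator):
    """Per-item random-intercept ordinal probit ICC estimator.

    Fits each column of ``X`` marginally: thresholds plus the cluster
    intercept variance ``tau2`` by adaptive-quadrature ML, giving the
    latent-response intraclass correlation ``tau2 / (tau2 + 1)``.

    Attributes
    ----------
    icc_ : (n_items,) latent-response ICC per item.
    tau2_ : (n_items,) cluster-intercept variances.
    thresholds_ : list of model-scale threshold vectors.
    icc_linear_ : (n_items,) one-way ANOVA ICC on the raw scores.
    """

    def __init__(self, n_nodes: int = 15):
        self.n_nodes = n_nodes

    def fit(self, X, y=None, groups=None, sample_weight=None):
        data = _build_dataset(X, groups, sample_weight)
        fits = [fit_item_probit(data, j, n_nodes=self.n_nodes)
                for j in range(data.n_items)]
        self.icc_ = np.array([f.icc for f in fits])
        self.tau2_ = np.array([f.tau2 for f in fits])
        self.thresholds_ = [f.thresholds for f in fits]
        self.converged_ = np.array([f.converged for f in fits])
        self.icc_linear_ = np.array([icc_linear(data, j) for j in range(data.n_items)])
        return self


class TwoLevelPolychoric(BaseEstimator):
    """Stage-1 estimator: thresholds plus within/between polychoric matrices.

    Attributes
    ----------
    corr_within_, corr_between_ : (M, M) polychoric correlation matrices.
    var_between_ : (M,) between latent variances (``icc/(1-icc)`` scale).
    thresholds_ : marginal standardized thresholds per item.
    moments_ : the full :class:`~mlfa.moments.TwoLevelMoments`.
    """

    def __init__(self, n_nodes: int = 15):
        self.n_nodes = n_nodes

    def fit(self, X, y=None, groups=None, sample_weight=None):
        data = _build_dataset(X, groups, sample_weight)
        mom = correlation_matrices(data, n_nodes=self.n_nodes)
        self.moments_ = mom
        self.corr_within_ = mom.R_W
        self.corr_between_ = mom.R_B
        self.var_between_ = mom.var_B
        self.thresholds_ = mom.thresholds
        self.pair_n_ = mom.pair_n
        self.flags_ = mom.flags
        return self


class MultilevelFactorAnalysis(BaseEstimator):
    """Two-level ordinal factor analysis (ML-EFA / ML-CFA / HLVM).

    Runs the two-stage limited-information pipeline: two-level polychoric
    decomposition of ``X`` (stage 1), then least-squares fitting of the
    requested measurement model to the within and between matrices
    (stage 2).

    Parameters
    ----------
    n_factors_within, n_factors_between : factor counts per level.
    mode : 'efa' or 'cfa'.
    pattern_within, pattern_between : binary loading masks (CFA only).
    constraints : iterable of constraint names; e.g.
        ``('cross_level_equal_loadings', 'no_between_residuals')`` gives the
        hierarchical latent variable model.
    rotation_epsilon, oblique : geomin rotation settings (EFA).
    n_nodes : quadrature nodes per dimension in stage 1.
    n_starts : stage-2 multi-start count.
    random_state : seed for stage-2 starts and rotation starts.

    Attributes (after ``fit``)
    ----------
    loadings_within_ : (M, p_W) rotated standardized within loadings.
    factor_corr_within_ : (p_W, p_W) within factor correlations.
    loadings_between_ : (M, p_B) between loadings, standardized at the
        between level.
    chi2_, df_, p_value_, cfi_, rmsea_, srmr_within_, srmr_between_ : fit
        statistics (chi2 is a ULS-style approximation).
    communalities_within_, communalities_between_ : per-item R^2 by level.
    result_ : the full :class:`~mlfa.fitting.FitResult`.
    moments_ : stage-1 :class:`~mlfa.moments.TwoLevelMoments`.
    """

    def __init__(self, n_factors_within: int = 2, n_factors_between: int = 1,
                 mode: str = "efa", pattern_within=None, pattern_between=None,
                 constraints=(), rotation_epsilon: float = 0.01, oblique: bool = True,
                 n_nodes: int = 15, n_starts: int = 3, random_state: int = 0):
        self.n_factors_within = n_factors_within
        self.n_factors_between = n_factors_between
        self.mode = mode
        self.pattern_within = pattern_within
        self.pattern_between = pattern_between
        self.constraints = constraints
        self.rotation_epsilon = rotation_epsilon
        self.oblique = oblique
        self.n_nodes = n_nodes
        self.n_starts = n_starts
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            p_W=self.n_factors_within, p_B=self.n_factors_between,
            mode=self.mode,
            pattern_W=self.pattern_within, pattern_B=self.pattern_between,
            constraints=frozenset(self.constraints),
            rotation={"method": "geomin", "epsilon": self.rotation_epsilon,
                      "oblique": self.oblique},
        )

    def fit(self, X, y=None, groups=None, sample_weight=None):
        data = _build_dataset(X, groups, sample_weight)
        moments = correlation_matrices(data, n_nodes=self.n_nodes)
        return self.fit_from_moments(moments, n_obs=data.n_obs)

    def fit_from_moments(self, moments, n_obs: int = None):
        """Stage-2 only: fit the model to precomputed stage-1 moments."""
        res = fit_mlfa(moments, self._spec(), N=n_obs, n_starts=self.n_starts,
                       seed=self.random_state)
        self.moments_ = moments
        self.result_ = res
        self.loadings_within_ = res.lambda_W_hat
        self.factor_corr_within_ = res.psi_W_hat
        self.loadings_between_ = res.lambda_B_std
        self.residual_var_within_ = res.theta_W_hat
        self.residual_var_between_ = res.theta_B_hat
        self.discrepancy_ = res.discrepancy
        self.chi2_ = res.chi2
        self.df_ = res.df
        self.p_value_ = res.p_value
        self.cfi_ = res.cfi
        self.rmsea_ = res.rmsea
        self.srmr_within_ = res.srmr_W
        self.srmr_between_ = res.srmr_B
        self.communalities_within_ = res.communality_W
        self.communalities_between_ = res.communality_B
        self.converged_ = res.converged
        return self

    def score(self, X=None, y=None) -> float:
        """Negative discrepancy of the fitted model (higher is better)."""
        return -float(self.discrepancy_)
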