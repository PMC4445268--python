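"""Stage 2: least-squares fitting of two-level measurement models.

Given the stage-1 moments (within correlations ``R_W``, between covariances
``Sigma_B`` on the within-standardized scale, thresholds held fixed), a
model spec is fit by minimizing the unweighted least-squares discrepancy

    F = 1/2 ||R_W - Sigma_W(theta)||_F^2 + 1/2 ||Sigma_B - Sigma_B(theta)||_F^2.

The within diagonal is reproduced exactly through the delta convention
(``theta_W = 1 - diag(Lambda_W Psi_W Lambda_W')``, clipped at zero with a
Heywood flag), so only off-diagonal within residuals carry information.
``chi2 = (N - 1) F`` is a documented ULS-style approximation — it supports
relative model comparison and the usual fit indices, but is not the
mean/variance-adjusted categorical test statistic of full-weight-matrix
estimators, so its absolute calibration should not be over-read.

For specs without cross-level constraints the within and between problems
separate and are solved independently; the HLVM variants couple the levels
and are fit jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.optimize import least_squares

from .model import ModelSpec, count_df, parameter_ledger
from .moments import TwoLevelMoments
from .rotation import geomin_rotate

__all__ = [
    "FitResult",
    "fit_mlfa",
    "fit_indices",
    "communalities",
    "residual_matrices",
    "compare_models",
    "baseline_discrepancy",
]

_OFF = lambda M: np.tril_indices(M, k=-1)


# ---------------------------------------------------------------------------
# correlation-Cholesky parameterization (unit-diagonal PSD)
# ---------------------------------------------------------------------------

def _corr_chol(x, p):
    """Unconstrained vector -> correlation matrix via row-normalized Cholesky."""
    L = np.eye(p)
    idx = np.tril_indices(p, k=-1)
    L[idx] = x
    norms = np.sqrt(np.sum(L**2, axis=1))
    L = L / norms[:, None]
    return L @ L.T


def _cov_chol(x, p):
    """Unconstrained vector -> PSD covariance via Cholesky with log-diagonal."""
    L = np.zeros((p, p))
    L[np.diag_indices(p)] = np.exp(x[:p])
    L[np.tril_indices(p, k=-1)] = x[p:]
    return L @ L.T


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Stage-2 estimates, discrepancy, fit indices, and residuals."""

    spec: ModelSpec
    n_obs: int
    lambda_W_hat: np.ndarray
    psi_W_hat: np.ndarray
    theta_W_hat: np.ndarray
    lambda_B_hat: np.ndarray
    psi_B_hat: np.ndarray
    theta_B_hat: np.ndarray
    lambda_B_std: np.ndarray      # between loadings standardized at the between level
    discrepancy: float
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    srmr_W: float
    srmr_B: float
    residual_W: np.ndarray
    residual_B: np.ndarray
    communality_W: np.ndarray
    communality_B: np.ndarray
    converged: bool
    heywood: bool
    ledger: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"model: {self.spec.mode.upper()} p_W={self.spec.p_W} p_B={self.spec.p_B} "
            f"constraints={sorted(self.spec.constraints) or 'none'}",
            f"chi2 = {self.chi2:.3f}; df = {self.df}; p = {self.p_value:.5g}; "
            f"CFI = {self.cfi:.3f}; RMSEA = {self.rmsea:.3f}; "
            f"SRMRwithin = {self.srmr_W:.3f}; SRMRbetween = {self.srmr_B:.3f}",
        ]
        if self.heywood:
            lines.append("warning: Heywood case flagged (communality at bound)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-level implied structures
# ---------------------------------------------------------------------------

def _implied_within(lam, psi):
    S = lam @ psi @ lam.T
    h2 = np.diag(S).copy()
    theta = np.clip(1.0 - h2, 0.0, None)
    np.fill_diagonal(S, h2 + theta)       # = 1 unless Heywood
    return S, theta


# ---------------------------------------------------------------------------
# fitting engines
# ---------------------------------------------------------------------------

def _fit_within(R_W, spec, rng, n_starts):
    """Separable within-level fit. Returns (lam, psi, F_contrib, converged)."""
    M = R_W.shape[0]
    p = spec.p_W
    off = _OFF(M)

    if spec.mode == "efa":
        def unpack(x):
            return x.reshape(M, p), np.eye(p)
    else:
        pat = spec.pattern_W
        nl = int(pat.sum())
        nc = p * (p - 1) // 2

        def unpack(x):
            lam = np.zeros((M, p))
            lam[pat] = x[:nl]
            psi = _corr_chol(x[nl:nl + nc], p)
            return lam, psi

    def resid(x):
        lam, psi = unpack(x)
        S, _ = _implied_within(lam, psi)
        return np.sqrt(2.0) * (R_W - S)[off]

    # principal-axis start
    w, V = np.linalg.eigh(R_W)
    lam0 = V[:, -p:][:, ::-1] * np.sqrt(np.clip(w[-p:][::-1], 0, None))
    starts = []
    if spec.mode == "efa":
        starts.append(lam0.ravel())
        for _ in range(n_starts - 1):
            starts.append(lam0.ravel() + 0.2 * rng.standard_normal(M * p))
    else:
        x0 = np.concatenate([0.6 * np.ones(int(spec.pattern_W.sum())),
                             np.zeros(p * (p - 1) // 2)])
        starts.append(x0)
        for _ in range(n_starts - 1):
            starts.append(x0 + 0.2 * rng.standard_normal(len(x0)))

    best = None
    for x0 in starts:
        res = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    lam, psi = unpack(best.x)
    return lam, psi, float(best.cost), True


def _fit_between(Sigma_B, spec, rng, n_starts):
    """Separable between-level fit with free item residuals."""
    M = Sigma_B.shape[0]
    p = spec.p_B
    free_theta = "no_between_residuals" not in spec.constraints
    if spec.mode == "efa":
        nl = M * p
        pat = None
    else:
        pat = spec.pattern_B
        nl = int(pat.sum())
    nc = 0 if spec.mode == "efa" else p * (p - 1) // 2

    def unpack(x):
        if pat is None:
            lam = x[:nl].reshape(M, p)
            psi = np.eye(p)
        else:
            lam = np.zeros((M, p))
            lam[pat] = x[:nl]
            psi = _corr_chol(x[nl:nl + nc], p)
        theta = x[nl + nc:] if free_theta else np.zeros(M)
        return lam, psi, theta

    iu = np.triu_indices(M)
    wts = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))

    def resid(x):
        lam, psi, theta = unpack(x)
        S = lam @ psi @ lam.T + np.diag(theta)
        return wts * (Sigma_B - S)[iu]

    d = np.sqrt(np.clip(np.diag(Sigma_B), 1e-8, None))
    Rb = Sigma_B / np.outer(d, d)
    w, V = np.linalg.eigh(Rb)
    lam0 = (V[:, -p:][:, ::-1] * np.sqrt(np.clip(w[-p:][::-1], 0, None))) * d[:, None]
    th0 = 0.3 * np.diag(Sigma_B)
    starts = []
    if pat is None:
        lam_start = lam0.ravel()
    else:
        lam_start = (0.8 * d[:, None] * np.ones((M, p)))[pat]
    base = np.concatenate([lam_start, np.zeros(nc),
                           th0 if free_theta else np.zeros(0)])
    starts.append(base)
    for _ in range(n_starts - 1):
        pert = base.copy()
        pert[:nl + nc] += 0.2 * rng.standard_normal(nl + nc)
        starts.append(pert)

    lb = np.full(len(base), -np.inf)
    ub = np.full(len(base), np.inf)
    if free_theta:
        lb[nl + nc:] = 0.0
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-10, ub)
        res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    lam, psi, theta = unpack(best.x)
    return lam, psi, np.asarray(theta, dtype=float) if free_theta else np.zeros(M), float(best.cost), True


def _fit_joint_hlvm(R_W, Sigma_B, spec, rng, n_starts):
    """Cross-level constrained fits (HLVM / strict variant), joint levels."""
    M = R_W.shape[0]
    p = spec.p_W
    pat = spec.pattern_W
    fixed_one = "loadings_fixed_one" in spec.constraints
    markers = np.array([np.argmax(pat[:, q]) for q in range(p)])
    free_mask = pat.copy()
    if not fixed_one:
        free_mask[markers, np.arange(p)] = False
    nl = 0 if fixed_one else int(free_mask.sum())
    ncov = p * (p + 1) // 2

    def unpack(x):
        lam = pat.astype(float) if fixed_one else np.zeros((M, p))
        if not fixed_one:
            lam[markers, np.arange(p)] = 1.0
            lam[free_mask] = x[:nl]
        psi_W = _cov_chol(x[nl:nl + ncov], p)
        psi_B = _cov_chol(x[nl + ncov:nl + 2 * ncov], p)
        return lam, psi_W, psi_B

    off = _OFF(M)
    iu = np.triu_indices(M)
    wts = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    equal_theta = "equal_within_residuals" in spec.constraints

    def resid(x):
        lam, psi_W, psi_B = unpack(x)
        SW = lam @ psi_W @ lam.T
        h2 = np.diag(SW).copy()
        if equal_theta:
            theta = np.full(M, np.clip(np.mean(1.0 - h2), 0.0, None))
        else:
            theta = np.clip(1.0 - h2, 0.0, None)
        SW = SW + np.diag(theta)
        SB = lam @ psi_B @ lam.T
        r_w_off = np.sqrt(2.0) * (R_W - SW)[off]
        r_w_diag = np.diag(R_W) - np.diag(SW)
        r_b = wts * (Sigma_B - SB)[iu]
        return np.concatenate([r_w_off, r_w_diag, r_b])

    # start: within CFA-style loadings scaled to marker metric
    x0 = np.concatenate([
        np.full(nl, 0.8),
        np.concatenate([0.5 * np.log(0.4 * np.ones(p)), np.zeros(p * (p - 1) // 2)]),
        np.concatenate([0.5 * np.log(0.1 * np.ones(p)), np.zeros(p * (p - 1) // 2)]),
    ])
    starts = [x0]
    for _ in range(n_starts - 1):
        starts.append(x0 + 0.2 * rng.standard_normal(len(x0)))
    best = None
    for s in starts:
        res = least_squares(resid, s, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    lam, psi_W, psi_B = unpack(best.x)
    return lam, psi_W, psi_B, float(best.cost), True


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def baseline_discrepancy(moments: TwoLevelMoments):
    """Independence baseline at both levels: zero loadings, free thresholds,
    between residuals matching the between variances."""
    M = moments.R_W.shape[0]
    off = _OFF(M)
    Sigma_B = moments.Sigma_B
    F = float(np.sum(moments.R_W[off] ** 2) + np.sum((Sigma_B - np.diag(np.diag(Sigma_B)))[off] ** 2))
    K = moments.n_categories
    stats = int(np.sum(K - 1)) + M * (M - 1) // 2 + M * (M + 1) // 2
    df = stats - int(np.sum(K - 1)) - M
    return F, df


def fit_mlfa(moments: TwoLevelMoments, spec: ModelSpec, N: int = None,
             n_starts: int = 3, seed: int = 0, rotate: bool = True) -> FitResult:
    """Fit a two-level measurement model to stage-1 moments.

    ``N`` defaults to the moments' within-level sample size (number of
    individuals), the convention used in ``chi2`` and RMSEA.
    """
    if N is None:
        N = moments.n_obs
    R_W = np.asarray(moments.R_W, dtype=float)
    Sigma_B = moments.Sigma_B
    if np.any(np.isnan(R_W)) or np.any(np.isnan(Sigma_B)):
        raise ValueError("moments contain failed (NaN) entries; see moments.flags")
    M = R_W.shape[0]
    rng = np.random.default_rng(seed)

    if spec.is_hlvm:
        lam, psi_W, psi_B, F, conv = _fit_joint_hlvm(R_W, Sigma_B, spec, rng, n_starts)
        lam_W = lam_B = lam
        theta_B = np.zeros(M)
    else:
        lam_W, psi_W, F_w, conv_w = _fit_within(R_W, spec, rng, n_starts)
        lam_B, psi_B, theta_B, F_b, conv_b = _fit_between(Sigma_B, spec, rng, n_starts)
        F = F_w + F_b
        conv = conv_w and conv_b

    SW, theta_W = _implied_within(lam_W, psi_W)
    heywood = bool(np.any(np.diag(lam_W @ psi_W @ lam_W.T) > 1 + 1e-8))
    SB = lam_B @ psi_B @ lam_B.T + np.diag(theta_B)

    # EFA reporting rotation (indices are rotation invariant)
    if rotate and spec.mode == "efa":
        rot = spec.rotation
        if spec.p_W >= 1:
            lam_W, psi_W = geomin_rotate(lam_W, epsilon=rot.get("epsilon", 0.01),
                                         oblique=rot.get("oblique", True))
        if spec.p_B >= 1:
            lam_B, psi_B_corr = geomin_rotate(lam_B, epsilon=rot.get("epsilon", 0.01),
                                              oblique=rot.get("oblique", True))
            psi_B = psi_B_corr

    df = count_df(spec, M, moments.n_categories)
    F_base, df_base = baseline_discrepancy(moments)
    chi2, p, cfi, rmsea, srmr_W, srmr_B = fit_indices(
        F, df, F_base, df_base, N, R_W, SW, moments.R_B, SB)

    res_W, res_B = _residuals(R_W, SW, moments.R_B, SB)
    comm_W = np.clip(np.diag(lam_W @ psi_W @ lam_W.T), 0, None)
    dB = np.diag(SB)
    with np.errstate(invalid="ignore", divide="ignore"):
        comm_B = np.where(dB > 0, np.diag(lam_B @ psi_B @ lam_B.T) / dB, 0.0)
        lam_B_std = lam_B / np.sqrt(dB)[:, None]
    if heywood:
        warnings.warn("Heywood case: a within communality exceeds 1", RuntimeWarning)

    return FitResult(
        spec=spec, n_obs=N,
        lambda_W_hat=lam_W, psi_W_hat=psi_W, theta_W_hat=theta_W,
        lambda_B_hat=lam_B, psi_B_hat=psi_B, theta_B_hat=theta_B,
        lambda_B_std=lam_B_std,
        discrepancy=F, chi2=chi2, df=df, p_value=p, cfi=cfi, rmsea=rmsea,
        srmr_W=srmr_W, srmr_B=srmr_B,
        residual_W=res_W, residual_B=res_B,
        communality_W=comm_W, communality_B=np.clip(comm_B, 0, None),
        converged=conv, heywood=heywood,
        ledger=parameter_ledger(spec, M, moments.n_categories),
    )


def _cov2corr(S):
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    return S / np.outer(d, d)


def _residuals(R_W, SW, R_B, SB):
    res_W = R_W - SW
    res_B = R_B - _cov2corr(SB)
    return res_W, res_B


def residual_matrices(fit: FitResult, moments: TwoLevelMoments):
    """Stage-1 minus model-implied correlation matrices, per level."""
    SW, _ = _implied_within(fit.lambda_W_hat, fit.psi_W_hat)
    SB = fit.lambda_B_hat @ fit.psi_B_hat @ fit.lambda_B_hat.T + np.diag(fit.theta_B_hat)
    return _residuals(moments.R_W, SW, moments.R_B, SB)


def fit_indices(F, df, F_base, df_base, N, R_W, SW, R_B, SB):
    """chi2, p, CFI, RMSEA and per-level SRMR from the discrepancies.

    ``chi2 = (N-1) F``; ``CFI = 1 - max(chi2-df,0)/max(chi2_b-df_b, chi2-df, 0)``;
    ``RMSEA = sqrt(max(chi2-df, 0)/(df (N-1)))``; SRMR at each level is the
    root mean square of the off-diagonal residual correlations.
    """
    chi2 = (N - 1) * F
    chi2_b = (N - 1) * F_base
    p = float(sstats.chi2.sf(chi2, df)) if df > 0 else 1.0
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_base, chi2 - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    rmsea = np.sqrt(num / (df * (N - 1))) if df > 0 else np.nan
    res_W, res_B = _residuals(R_W, SW, R_B, SB)
    M = R_W.shape[0]
    off = _OFF(M)
    srmr_W = float(np.sqrt(np.mean(res_W[off] ** 2)))
    srmr_B = float(np.sqrt(np.mean(res_B[off] ** 2)))
    return float(chi2), p, float(cfi), float(rmsea), srmr_W, srmr_B


def communalities(fit: FitResult):
    """Per-item variance shares explained by the factors, per level."""
    return fit.communality_W.copy(), fit.communality_B.copy()


def communality_from_loadings(loadings, factor_corr=None):
    """Standardized communalities ``h^2 = diag(L Phi L')`` per item.

    For oblique standardized loadings ``L`` (items x factors) and factor
    correlation ``Phi``; with one factor this reduces to the squared loading.
    """
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[0] == 1 and L.size > 1 and factor_corr is None:
        L = L.T
    p = L.shape[1]
    Phi = np.eye(p) if factor_corr is None else np.atleast_2d(np.asarray(factor_corr))
    return np.einsum("ik,kl,il->i", L, Phi, L)


def compare_models(fit_a: FitResult, fit_b: FitResult) -> dict:
    """Ordering report for two fits on the same moments and N.

    When one spec is a constrained version of the other, asserts that the
    constrained discrepancy is no smaller (nested-model monotonicity).
    """
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("fits must share the same sample size")
    nested = fit_b.spec.nested_in(fit_a.spec) or fit_a.spec.nested_in(fit_b.spec)
    if fit_b.spec.nested_in(fit_a.spec):
        restricted, general = fit_b, fit_a
    else:
        restricted, general = fit_a, fit_b
    report = {
        "nested": nested,
        "delta_discrepancy": restricted.discrepancy - general.discrepancy,
        "delta_df": restricted.df - general.df,
        "delta_chi2": restricted.chi2 - general.chi2,
        "indices": {
            "cfi": (general.cfi, restricted.cfi),
            "rmsea": (general.rmsea, restricted.rmsea),
            "srmr_W": (general.srmr_W, restricted.srmr_W),
            "srmr_B": (general.srmr_B, restricted.srmr_B),
        },
    }
    if nested and report["delta_discrepancy"] < -1e-8:
        raise AssertionError(
            "nested-model monotonicity violated: constrained fit has a lower "
            f"discrepancy ({restricted.discrepancy:.6g} < {general.discrepancy:.6g})")
    return report
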