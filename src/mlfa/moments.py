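"""Stage 1: thresholds and within/between polychoric correlation matrices.

Estimation is two-stage limited information.  First each item is fit
marginally (thresholds) and as a random-intercept ordinal probit (between
variance ``v_m = tau2_m``).  Then, holding those fixed, every item pair gets
a bivariate random-intercept ordinal probit

    y*_a = u_a + e_a,  y*_b = u_b + e_b,
    (u_a, u_b) ~ N2(0, V_B),   V_B offdiag = r_B sqrt(v_a v_b),
    (e_a, e_b) ~ N2(0, [[1, r_W], [r_W, 1]]),

whose two free parameters ``(r_W, r_B)`` — the within-level and
between-level polychoric correlations — are estimated by maximum likelihood
with two-dimensional adaptive Gauss-Hermite quadrature over the cluster
intercepts.  The between prior density is the only term involving ``r_B``,
so the optimizer profiles it: each trial value of ``r_W`` pays for the
expensive bivariate cell probabilities once, and the inner maximization over
``r_B`` reuses them.

Missing data are handled pairwise-present: each pair uses every observation
with both items observed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .bvn import rectangle_probabilities
from .data import OrdinalDataset
from .icc import ItemProbitFit, cluster_counts, cluster_modes, fit_item_probit

logger = logging.getLogger(__name__)

__all__ = [
    "TwoLevelMoments",
    "estimate_thresholds",
    "pairwise_polychoric_twolevel",
    "PairwiseLikelihood",
    "correlation_matrices",
    "pooled_within_between_cov",
    "summarize_correlations",
    "nearest_psd_corr",
    "DegenerateItemError",
]

_SQRT2 = np.sqrt(2.0)
_RMAX = 0.995


class DegenerateItemError(ValueError):
    """An item lacks the variation the requested estimate needs."""


# ---------------------------------------------------------------------------
# marginal thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(data: OrdinalDataset, item: int) -> np.ndarray:
    """Marginal probit thresholds: inverse-normal weighted cumulative
    proportions, on the standardized total latent-response scale."""
    y = data.responses[:, item]
    keep = ~np.isnan(y)
    y, w = y[keep], data.weight[keep]
    K = int(data.n_categories[item])
    tot = np.zeros(K)
    np.add.at(tot, y.astype(int) - 1, w)
    if np.count_nonzero(tot) < 2:
        raise DegenerateItemError(
            f"item {data.item_labels[item]!r} has fewer than 2 observed categories")
    zero = np.where(tot == 0)[0]
    if zero.size:
        raise DegenerateItemError(
            f"item {data.item_labels[item]!r}: category {zero[0] + 1} has zero total "
            "weight; adjacent thresholds would collapse")
    cum = np.cumsum(tot)[:-1] / tot.sum()
    return norm.ppf(cum)


# ---------------------------------------------------------------------------
# pairwise two-level polychoric
# ---------------------------------------------------------------------------

def _pair_tables(data: OrdinalDataset, a: int, b: int):
    """Weighted per-cluster two-way tables on pairwise-present rows."""
    ya, yb = data.responses[:, a], data.responses[:, b]
    keep = ~np.isnan(ya) & ~np.isnan(yb)
    if not np.any(keep):
        raise DegenerateItemError(
            f"no pairwise-present observations for items "
            f"{data.item_labels[a]!r}, {data.item_labels[b]!r}")
    ya, yb = ya[keep].astype(int) - 1, yb[keep].astype(int) - 1
    cl, w = data.cluster_id[keep], data.weight[keep]
    w = w * (len(w) / w.sum())
    labs = np.unique(cl)
    Ka, Kb = int(data.n_categories[a]), int(data.n_categories[b])
    tab = np.zeros((len(labs), Ka, Kb))
    idx = np.searchsorted(labs, cl)
    np.add.at(tab, (idx, ya, yb), w)
    return tab, labs, int(keep.sum())


class PairwiseLikelihood:
    """Profiled AGH log-likelihood of one item pair.

    Exposes ``loglik(r_W, r_B)`` so that the ML route and brute-force grid
    search share one likelihood; used directly by the fitting code and by
    oracle tests.
    """

    def __init__(self, data: OrdinalDataset, a: int, b: int,
                 stage1_a: ItemProbitFit, stage1_b: ItemProbitFit, n_nodes=15):
        tab, labs, n_pair = _pair_tables(data, a, b)
        # drop categories unobserved in the full data (matches the stage-1
        # threshold count when codes were relabeled or never used)
        if stage1_a.observed_mask is not None:
            tab = tab[:, stage1_a.observed_mask, :]
        if stage1_b.observed_mask is not None:
            tab = tab[:, :, stage1_b.observed_mask]
        self.tables = tab
        self.n_pair = n_pair
        self.cuts_a = np.asarray(stage1_a.thresholds, dtype=float)
        self.cuts_b = np.asarray(stage1_b.thresholds, dtype=float)
        self.v_a = max(stage1_a.tau2, 1e-6)
        self.v_b = max(stage1_b.tau2, 1e-6)

        for lab, name, cuts in ((a, data.item_labels[a], self.cuts_a),
                                (b, data.item_labels[b], self.cuts_b)):
            marg = tab.sum(axis=2) if lab == a else tab.sum(axis=1)
            within = np.any((marg > 0).sum(axis=1) > 1)
            if not within:
                raise DegenerateItemError(
                    f"item {name!r} shows no within-cluster variation; "
                    "the within-level correlation is undefined")

        # fixed adaptive centers/scales from the univariate posteriors
        counts_a = tab.sum(axis=2)
        counts_b = tab.sum(axis=1)
        m_a, s_a = cluster_modes(counts_a, self.cuts_a, self.v_a)
        m_b, s_b = cluster_modes(counts_b, self.cuts_b, self.v_b)
        z, wq = np.polynomial.hermite.hermgauss(n_nodes)
        self.x_a = m_a[:, None] + _SQRT2 * s_a[:, None] * z[None, :]   # (J, Q)
        self.x_b = m_b[:, None] + _SQRT2 * s_b[:, None] * z[None, :]
        lw = np.log(wq) + z**2
        # constant per (cluster, q1, q2) quadrature weight terms
        self.base = (
            np.log(_SQRT2 * s_a)[:, None, None] + np.log(_SQRT2 * s_b)[:, None, None]
            + lw[None, :, None] + lw[None, None, :]
        )
        self._cells_cache = (None, None)

    def _cell_loglik(self, r_W: float) -> np.ndarray:
        key, val = self._cells_cache
        if key == r_W:
            return val
        A = self.cuts_a[None, None, None, :] - self.x_a[:, :, None, None]   # (J,Q1,1,Ka-1)
        B = self.cuts_b[None, None, None, :] - self.x_b[:, None, :, None]   # (J,1,Q2,Kb-1)
        p = rectangle_probabilities(A, B, r_W)                              # (J,Q1,Q2,Ka,Kb)
        out = np.einsum("jkl,jabkl->jab", self.tables, np.log(p))
        self._cells_cache = (r_W, out)
        return out

    def _log_prior(self, r_B: float) -> np.ndarray:
        c = r_B * np.sqrt(self.v_a * self.v_b)
        det = self.v_a * self.v_b - c * c
        ia, ib, ic = self.v_b / det, self.v_a / det, -c / det
        xa = self.x_a[:, :, None]
        xb = self.x_b[:, None, :]
        quad = ia * xa**2 + ib * xb**2 + 2 * ic * xa * xb
        return -0.5 * quad - 0.5 * np.log((2 * np.pi) ** 2 * det)

    def loglik(self, r_W: float, r_B: float) -> float:
        """Marginal log-likelihood at the given correlations."""
        terms = self.base + self._cell_loglik(float(r_W)) + self._log_prior(float(r_B))
        return float(np.sum(logsumexp(terms, axis=(1, 2))))

    def profile_r_B(self, r_W: float):
        """Maximize over ``r_B`` at fixed ``r_W`` (cells are reused)."""
        cells = self.base + self._cell_loglik(float(r_W))

        def nll(r_B):
            t = cells + self._log_prior(float(r_B))
            return -float(np.sum(logsumexp(t, axis=(1, 2))))

        res = minimize_scalar(nll, bounds=(-_RMAX, _RMAX), method="bounded",
                              options={"xatol": 1e-5})
        return float(res.x), -float(res.fun)


@dataclass
class PairFit:
    r_W: float
    r_B: float
    loglik: float
    n_pair: int
    converged: bool = True
    flag: str = ""


def pairwise_polychoric_twolevel(data: OrdinalDataset, item_a: int, item_b: int,
                                 stage1=None, n_nodes=15) -> PairFit:
    """ML two-level polychoric correlations for one item pair.

    ``stage1`` is an optional pair (or full per-item list) of
    :class:`~mlfa.icc.ItemProbitFit`; fitted on the fly when omitted.
    """
    if stage1 is None:
        s_a = fit_item_probit(data, item_a, n_nodes=n_nodes)
        s_b = fit_item_probit(data, item_b, n_nodes=n_nodes)
    elif len(stage1) == data.n_items:
        s_a, s_b = stage1[item_a], stage1[item_b]
    else:
        s_a, s_b = stage1
    lik = PairwiseLikelihood(data, item_a, item_b, s_a, s_b, n_nodes=n_nodes)

    best = {}

    def outer(r_W):
        r_B, ll = lik.profile_r_B(float(r_W))
        if not best or ll > best["ll"]:
            best.update(r_W=float(r_W), r_B=r_B, ll=ll)
        return -ll

    minimize_scalar(outer, bounds=(-_RMAX, _RMAX), method="bounded",
                    options={"xatol": 1e-4})
    flag = ""
    if max(abs(best["r_W"]), abs(best["r_B"])) > 0.99:
        flag = "boundary estimate (|r| > 0.99)"
        warnings.warn(f"two-level polychoric pair ({item_a}, {item_b}): {flag}",
                      RuntimeWarning)
    return PairFit(r_W=best["r_W"], r_B=best["r_B"], loglik=best["ll"],
                   n_pair=lik.n_pair, converged=True, flag=flag)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def nearest_psd_corr(R: np.ndarray, floor: float = 1e-6):
    """Eigenvalue-clipped nearest PSD repair, rescaled to unit diagonal.

    Returns ``(repaired, changed)``.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() >= floor:
        return R.copy(), False
    w = np.clip(w, floor, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d), True


@dataclass
class TwoLevelMoments:
    """Stage-1 estimates feeding the stage-2 factor model fits."""

    thresholds: list                 # marginal standardized cutpoints per item
    thresholds_model: list           # within-standardized (model-scale) cutpoints
    R_W: np.ndarray                  # within-level polychoric correlations
    R_B: np.ndarray                  # between-level polychoric correlations
    var_B: np.ndarray                # between latent variances (icc/(1-icc) scale)
    pair_n: np.ndarray               # pairwise-present counts
    n_obs: int
    n_clusters: int
    item_labels: list
    n_categories: np.ndarray
    flags: dict = field(default_factory=dict)

    @property
    def Sigma_B(self) -> np.ndarray:
        """Between covariance on the within-standardized scale."""
        d = np.sqrt(self.var_B)
        return self.R_B * np.outer(d, d)

    def write_csv(self, dir_path, prefix=""):
        """Lower-triangle CSV writers for R_W and R_B."""
        import pathlib

        dir_path = pathlib.Path(dir_path)
        for name, R in (("within", self.R_W), ("between", self.R_B)):
            df = pd.DataFrame(np.round(R, 3), index=self.item_labels,
                              columns=self.item_labels)
            mask = np.triu(np.ones_like(R, dtype=bool), k=1)
            df = df.mask(mask, "")
            df.to_csv(dir_path / f"{prefix}correlations_{name}.csv")


def correlation_matrices(data: OrdinalDataset, n_nodes=15, stage1=None) -> TwoLevelMoments:
    """Assemble all pairwise two-level polychoric fits into matrices.

    Pairwise-present observations are used per pair; if the assembled
    matrix at either level is not PSD it is repaired by eigenvalue clipping
    (logged, recorded in ``flags``).
    """
    M = data.n_items
    if stage1 is None:
        stage1 = [fit_item_probit(data, j, n_nodes=n_nodes) for j in range(M)]
    R_W = np.eye(M)
    R_B = np.eye(M)
    pair_n = np.zeros((M, M), dtype=int)
    np.fill_diagonal(pair_n, [int(np.sum(~np.isnan(data.responses[:, j]))) for j in range(M)])
    flags = {}
    for a in range(M):
        for b in range(a + 1, M):
            try:
                fit = pairwise_polychoric_twolevel(data, a, b, stage1=(stage1[a], stage1[b]),
                                                   n_nodes=n_nodes)
            except DegenerateItemError as exc:
                flags[(a, b)] = str(exc)
                R_W[a, b] = R_W[b, a] = np.nan
                R_B[a, b] = R_B[b, a] = np.nan
                continue
            R_W[a, b] = R_W[b, a] = fit.r_W
            R_B[a, b] = R_B[b, a] = fit.r_B
            pair_n[a, b] = pair_n[b, a] = fit.n_pair
            if fit.flag:
                flags[(a, b)] = fit.flag
    for name, R in (("within", R_W), ("between", R_B)):
        if not np.any(np.isnan(R)):
            rep, changed = nearest_psd_corr(R)
            if changed:
                logger.warning("%s correlation matrix repaired to nearest PSD", name)
                flags[f"psd_{name}"] = "eigenvalue-clipped to PSD"
                R[:] = rep
    return TwoLevelMoments(
        thresholds=[estimate_thresholds(data, j) for j in range(M)],
        thresholds_model=[s.thresholds for s in stage1],
        R_W=R_W, R_B=R_B,
        var_B=np.array([s.tau2 for s in stage1]),
        pair_n=pair_n, n_obs=data.n_obs, n_clusters=len(data.clusters),
        item_labels=list(data.item_labels), n_categories=data.n_categories.copy(),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# continuous-data / starting-value path
# ---------------------------------------------------------------------------

def pooled_within_between_cov(y: np.ndarray, cluster_id, weight=None):
    """Pooled within- and scaled between-cluster covariance matrices.

    ``S_PW = sum_j sum_i w (y - ybar_j)(y - ybar_j)' / (N - J)`` and
    ``S_B = sum_j n_j (ybar_j - ybar)(ybar_j - ybar)' / (J - 1)`` with the
    unbalanced-design constant ``c = (N^2 - sum n_j^2) / (N (J - 1))``;
    under the two-level model ``E[S_PW] = Sigma_W`` and
    ``E[S_B] = Sigma_W + c Sigma_B``.

    Returns ``(S_PW, S_B, c)``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.ndim == 2 and y.shape[0] == 1 and np.asarray(cluster_id).size != 1:
        y = y.T
    n, m = y.shape
    cluster_id = np.asarray(cluster_id)
    w = np.ones(n) if weight is None else np.asarray(weight, dtype=float)
    w = w * (n / w.sum())
    labs = np.unique(cluster_id)
    J = len(labs)
    if J < 2:
        raise ValueError("pooled decomposition requires at least 2 clusters")
    N = w.sum()
    if N - J <= 0:
        raise ValueError("pooled within covariance undefined: one observation per cluster")
    grand = np.average(y, axis=0, weights=w)
    SW = np.zeros((m, m))
    SB = np.zeros((m, m))
    nj = np.empty(J)
    for i, lab in enumerate(labs):
        sel = cluster_id == lab
        wj = w[sel]
        nj[i] = wj.sum()
        mean_j = np.average(y[sel], axis=0, weights=wj)
        d = y[sel] - mean_j
        SW += (d * wj[:, None]).T @ d
        db = mean_j - grand
        SB += nj[i] * np.outer(db, db)
    S_PW = SW / (N - J)
    S_B = SB / (J - 1)
    c = (N**2 - np.sum(nj**2)) / (N * (J - 1))
    return S_PW, S_B, c


def summarize_correlations(R: np.ndarray):
    """Mean/min/max absolute off-diagonal correlation (lower triangle).

    Returns ``(mean_abs, min_abs, max_abs)`` rounded to 3 decimals.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] < 2:
        raise ValueError("need a square correlation matrix with at least 2 items")
    if not np.allclose(np.diag(R), 1.0) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("input must be symmetric with unit diagonal")
    a = np.abs(R[np.tril_indices_from(R, k=-1)])
    return (round(float(a.mean()), 3), round(float(a.min()), 3), round(float(a.max()), 3))
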