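"""Per-item intraclass correlation for clustered ordinal items.

Two estimators are provided, because an ICC for an ordinal item can be taken
on either scale:

* ``icc_linear`` — one-way random-effects ANOVA on the integer scores
  (weighted, unbalanced-design constant ``c = (N^2 - sum n_j^2)/(N (J-1))``,
  negative estimates truncated to zero).
* ``icc_probit`` — maximum likelihood in a random-intercept ordinal probit
  model on the latent-response scale: ``y* = u_j + e``, ``u_j ~ N(0, tau2)``,
  ``e ~ N(0, 1)``, thresholds free; the likelihood integrates the cluster
  intercept by adaptive Gauss-Hermite quadrature and
  ``ICC = tau2 / (tau2 + 1)``.

The probit estimator is the package default, matching the ordinal treatment
of the rest of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtr
from scipy.stats import norm

from .data import OrdinalDataset

__all__ = ["icc_linear", "icc_probit", "icc_table", "IccTable", "fit_item_probit"]

_SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# linear (ANOVA) estimator
# ---------------------------------------------------------------------------

def _item_arrays(data: OrdinalDataset, item: int):
    y = data.responses[:, item]
    keep = ~np.isnan(y)
    if not np.any(keep):
        raise ValueError(f"item {data.item_labels[item]!r}: all responses missing")
    return y[keep], data.cluster_id[keep], data.weight[keep]


def icc_linear(data: OrdinalDataset, item: int) -> float:
    """One-way ANOVA intraclass correlation on the integer scores.

    Weights enter through weighted means and mean squares (normalized to sum
    to the number of used observations). Negative between-variance estimates
    are truncated to 0; a degenerate zero within-variance item returns 1
    (clipped just below 1 so the value stays in ``[0, 1)``).
    """
    y, cl, w = _item_arrays(data, item)
    labs = np.unique(cl)
    J = len(labs)
    if J < 2:
        raise ValueError("icc_linear requires at least 2 clusters with data")
    w = w * (len(y) / w.sum())  # normalize to sum N
    N = w.sum()
    grand = np.average(y, weights=w)
    ssb = 0.0
    ssw = 0.0
    nj = np.empty(J)
    for a, lab in enumerate(labs):
        m = cl == lab
        wj = w[m]
        nj[a] = wj.sum()
        mean_j = np.average(y[m], weights=wj)
        ssb += nj[a] * (mean_j - grand) ** 2
        ssw += np.sum(wj * (y[m] - mean_j) ** 2)
    msb = ssb / (J - 1)
    if N - J <= 0:
        raise ValueError("pooled within variance undefined: one observation per cluster")
    msw = ssw / (N - J)
    c = (N**2 - np.sum(nj**2)) / (N * (J - 1))
    if msw == 0.0:
        return 1.0 - 1e-12
    sigma_b = max((msb - msw) / c, 0.0)
    return float(sigma_b / (sigma_b + msw))


# ---------------------------------------------------------------------------
# random-intercept ordinal probit machinery (shared with the two-level
# polychoric module)
# ---------------------------------------------------------------------------

def cluster_counts(data: OrdinalDataset, item: int):
    """Weighted per-cluster category count matrix (J, K) for one item.

    Frequency-style weights, normalized to sum to the number of used
    observations so the likelihood scale is weight-scale invariant.
    """
    y, cl, w = _item_arrays(data, item)
    w = w * (len(y) / w.sum())
    labs = np.unique(cl)
    K = int(data.n_categories[item])
    counts = np.zeros((len(labs), K))
    idx = np.searchsorted(labs, cl)
    np.add.at(counts, (idx, y.astype(int) - 1), w)
    return counts, labs


def _cat_logp(cuts, u):
    """log P(category | u) for cutpoints ``cuts``; u broadcastable."""
    up = ndtr(cuts - u[..., None])           # (..., K-1)
    cum = np.concatenate(
        [np.zeros(up.shape[:-1] + (1,)), up, np.ones(up.shape[:-1] + (1,))], axis=-1
    )
    return np.log(np.clip(np.diff(cum, axis=-1), 1e-300, 1.0))


def cluster_modes(counts, cuts, v, max_iter=40, tol=1e-10):
    """Per-cluster Laplace mode and curvature scale of the random intercept.

    Maximizes ``-u^2/(2v) + sum_k n_k log p_k(u)`` by damped Newton,
    vectorized over clusters. Returns ``(mode, scale)`` with
    ``scale = (-f'')^{-1/2}``.
    """
    J, K = counts.shape
    cuts = np.asarray(cuts, dtype=float)
    u = np.zeros(J)
    for _ in range(max_iter):
        edge = cuts[None, :] - u[:, None]               # (J, K-1)
        pdf = norm.pdf(edge)
        cdf = ndtr(edge)
        p = np.diff(np.concatenate([np.zeros((J, 1)), cdf, np.ones((J, 1))], axis=1), axis=1)
        p = np.clip(p, 1e-300, 1.0)
        pdf_full = np.concatenate([np.zeros((J, 1)), pdf, np.zeros((J, 1))], axis=1)
        dp = pdf_full[:, :-1] - pdf_full[:, 1:]          # dp_k/du
        xphi = np.concatenate([np.zeros((J, 1)), edge * pdf, np.zeros((J, 1))], axis=1)
        d2p = xphi[:, :-1] - xphi[:, 1:]
        g = -u / v + np.sum(counts * dp / p, axis=1)
        h = -1.0 / v + np.sum(counts * (d2p * p - dp**2) / p**2, axis=1)
        h = np.minimum(h, -1e-8)
        step = np.clip(-g / h, -2.0, 2.0)
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    return u, 1.0 / np.sqrt(-h)


def item_loglik(counts, cuts, tau2, n_nodes=15):
    """Adaptive Gauss-Hermite marginal log-likelihood of one item.

    ``counts`` is the (J, K) weighted per-cluster category table, ``cuts``
    the model-scale thresholds, ``tau2`` the cluster-intercept variance.
    """
    tau2 = max(float(tau2), 1e-10)
    z, wq = np.polynomial.hermite.hermgauss(n_nodes)
    m, s = cluster_modes(counts, cuts, tau2)
    x = m[:, None] + _SQRT2 * s[:, None] * z[None, :]    # (J, Q)
    logp = _cat_logp(np.asarray(cuts, dtype=float), x)   # (J, Q, K)
    loglik_u = np.einsum("jk,jqk->jq", counts, logp)
    logprior = -0.5 * x**2 / tau2 - 0.5 * np.log(2 * np.pi * tau2)
    terms = (
        np.log(_SQRT2 * s[:, None]) + np.log(wq)[None, :] + z[None, :] ** 2
        + logprior + loglik_u
    )
    return float(np.sum(logsumexp(terms, axis=1)))


@dataclass
class ItemProbitFit:
    """ML fit of the random-intercept ordinal probit for a single item."""

    thresholds: np.ndarray  # model-scale (within-standardized) cutpoints
    tau2: float             # cluster-intercept variance
    icc: float              # tau2 / (tau2 + 1)
    loglik: float
    converged: bool
    n_used: int
    observed_mask: np.ndarray = None  # which of the declared categories occur


def _pack(cuts, tau2):
    cuts = np.asarray(cuts, dtype=float)
    d = np.diff(cuts)
    return np.concatenate([[cuts[0]], np.log(np.maximum(d, 1e-6)), [np.log(max(tau2, 1e-8))]])


def _unpack(theta, K):
    cuts = np.concatenate([[theta[0]], theta[0] + np.cumsum(np.exp(theta[1 : K - 1]))])
    return cuts, float(np.exp(theta[K - 1]))


def fit_item_probit(data: OrdinalDataset, item: int, n_nodes=15, n_restarts=2) -> ItemProbitFit:
    """Joint ML over thresholds and cluster variance for one item."""
    counts, _ = cluster_counts(data, item)
    tot = counts.sum(axis=0)
    if np.count_nonzero(tot) < 2:
        raise ValueError(f"item {data.item_labels[item]!r} has fewer than 2 observed categories")
    # collapse unobserved categories: the fit (and the ICC) depends only on
    # the ordered observed categories, making the estimator invariant to
    # order-preserving relabelings of the codes
    observed = tot > 0
    counts = counts[:, observed]
    tot = tot[observed]
    K = counts.shape[1]
    # starting values: marginal thresholds rescaled by the linear-ICC guess
    cum = np.clip(np.cumsum(tot)[:-1] / tot.sum(), 1e-4, 1 - 1e-4)
    icc0 = min(max(icc_linear(data, item), 1e-3), 0.6)
    tau0 = icc0 / (1 - icc0)
    cuts0 = norm.ppf(cum)
    # collapse ties from empty interior categories
    cuts0 = np.maximum.accumulate(cuts0 + 1e-6 * np.arange(K - 1))
    cuts0 = cuts0 * np.sqrt(1 + tau0)

    def nll(theta):
        cuts, tau2 = _unpack(theta, K)
        return -item_loglik(counts, cuts, tau2, n_nodes=n_nodes)

    best = None
    starts = [_pack(cuts0, tau0)]
    for r in range(1, n_restarts):
        starts.append(_pack(cuts0 * (1 + 0.1 * r), tau0 * (0.5 if r % 2 else 2.0)))
    for k, th0 in enumerate(starts):
        res = minimize(nll, th0, method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        if k == 0 and res.success:
            break
    if not best.success:
        warnings.warn(f"icc_probit: optimizer did not report convergence for "
                      f"item {data.item_labels[item]!r}", RuntimeWarning)
    cuts, tau2 = _unpack(best.x, K)
    n_used = int(np.sum(~np.isnan(data.responses[:, item])))
    return ItemProbitFit(
        thresholds=cuts, tau2=tau2, icc=tau2 / (tau2 + 1.0),
        loglik=-best.fun, converged=bool(best.success), n_used=n_used,
        observed_mask=observed,
    )


def icc_probit(data: OrdinalDataset, item: int, n_nodes=15):
    """Latent-response ICC of one item: returns ``(icc, tau2)``."""
    fit = fit_item_probit(data, item, n_nodes=n_nodes)
    return fit.icc, fit.tau2


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

@dataclass
class IccTable:
    """Per-item ICC table (optionally with split-half columns)."""

    table: pd.DataFrame

    def to_csv(self, path):
        self.table.to_csv(path, index=True, float_format="%.3f")


def _one_sample(data: OrdinalDataset, n_nodes):
    rows = []
    for j in range(data.n_items):
        row = {}
        try:
            row["icc_linear"] = icc_linear(data, j)
        except ValueError as exc:
            row["icc_linear"] = np.nan
            row["flag"] = str(exc)
        try:
            fit = fit_item_probit(data, j, n_nodes=n_nodes)
            row["icc_probit"] = fit.icc
            row["tau2"] = fit.tau2
            row["n_used"] = fit.n_used
            if not fit.converged:
                row["flag"] = "probit fit not converged"
        except ValueError as exc:
            row.update(icc_probit=np.nan, tau2=np.nan, n_used=0, flag=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows, index=data.item_labels)
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flag"] = df["flag"].fillna("")
    return df


def icc_table(data: OrdinalDataset, split=None, n_nodes=15) -> IccTable:
    """ICC table for the full sample, plus one column block per split half.

    ``split`` is an optional pair of :class:`OrdinalDataset` halves (as
    produced by :func:`mlfa.pipeline.split_sample`).
    """
    blocks = {"total": _one_sample(data, n_nodes)}
    if split is not None:
        for name, half in zip(("sample_1", "sample_2"), split):
            blocks[name] = _one_sample(half, n_nodes)
    df = pd.concat(blocks, axis=1)
    return IccTable(table=df)
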