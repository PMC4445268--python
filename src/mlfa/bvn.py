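"""Vectorized standard bivariate normal CDF via Owen's T function.

``Phi2(h, k, rho) = P(X <= h, Y <= k)`` for standard normal ``(X, Y)`` with
correlation ``rho``, using the exact identity

    Phi2(h,k,rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - delta

with ``a_h = (k - rho h) / (h sqrt(1-rho^2))`` (and symmetrically ``a_k``),
where ``delta = 1/2`` when ``h k < 0`` or exactly one of ``h, k`` is zero and
the other negative.  ``scipy.special.owens_t`` evaluates T elementwise in C,
which makes this orders of magnitude faster than looping a generic
multivariate-normal CDF — the two-level polychoric likelihood needs millions
of rectangle probabilities per fit.
"""

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "rectangle_probabilities"]

_EPS = 1e-13


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF, broadcasting over all arguments."""
    h, k, rho = np.broadcast_arrays(*np.atleast_1d(h, k, rho))
    h = np.asarray(h, dtype=float).copy()
    k = np.asarray(k, dtype=float).copy()
    rho = np.clip(np.asarray(rho, dtype=float), -0.99999, 0.99999)

    # nudge exact zeros so the Owen arguments stay finite; error O(1e-13)
    h[np.abs(h) < _EPS] = _EPS
    k[np.abs(k) < _EPS] = _EPS

    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    delta = np.where(h * k < 0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - delta
    return np.clip(out, 0.0, 1.0)


def rectangle_probabilities(a, b, rho):
    """Cell probabilities of a bivariate normal over a threshold grid.

    Parameters
    ----------
    a : (..., Ka - 1) ascending cutpoints on the first margin
    b : (..., Kb - 1) ascending cutpoints on the second margin
    rho : correlation, broadcastable against the leading axes

    Returns
    -------
    p : (..., Ka, Kb) probabilities of each rectangle, summing to 1 over the
        trailing two axes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lead = np.broadcast_shapes(a.shape[:-1], b.shape[:-1], np.shape(rho))
    Ka = a.shape[-1] + 1
    Kb = b.shape[-1] + 1
    a = np.broadcast_to(a, lead + (Ka - 1,))
    b = np.broadcast_to(b, lead + (Kb - 1,))
    rho_b = np.broadcast_to(np.asarray(rho, dtype=float), lead)

    # CDF grid including the +/- infinity borders
    F = np.zeros(lead + (Ka + 1, Kb + 1))
    F[..., -1, -1] = 1.0
    Fa = ndtr(a)
    Fb = ndtr(b)
    F[..., 1:-1, -1] = Fa
    F[..., -1, 1:-1] = Fb
    hh = a[..., :, None]
    kk = b[..., None, :]
    F[..., 1:-1, 1:-1] = bvn_cdf(hh, kk, rho_b[..., None, None])
    p = np.diff(np.diff(F, axis=-1), axis=-2)
    return np.clip(p, 1e-300, 1.0)
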