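"""Tail probabilities of positive mixtures of chi-square(1) variables.

``P(sum_i lambda_i chi2_1 > q)`` is computed by numerical inversion of the
characteristic function (Imhof's integral, the same quantity Davies'
method evaluates):

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du
    theta(u) = 0.5 * sum_i arctan(lambda_i u) - 0.5 * q * u
    rho(u)   = prod_i (1 + lambda_i^2 u^2)^(1/4)

with a moment-matched noncentral-chi-square approximation (Liu-Tang-Zhang,
skewness/kurtosis variant) as fallback whenever the integral misbehaves.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, ncx2


def _clean_eigenvalues(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float).ravel()
    if lam.size == 0:
        raise ValueError("need at least one eigenvalue")
    if np.any(lam < -1e-8 * max(1.0, np.abs(lam).max())):
        raise ValueError(f"negative eigenvalue in mixture: min={lam.min():.3g}")
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > 1e-14 * max(1.0, lam.max())]
    if lam.size == 0 or not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues are all zero or non-finite")
    # drop a trailing tail of negligible eigenvalues (< 1e-5 of the total
    # in sum); they slow the characteristic-function inversion without
    # moving the distribution measurably
    lam = np.sort(lam)[::-1]
    csum = np.cumsum(lam[::-1])[::-1]
    keep = csum > 1e-5 * lam.sum()
    return lam[keep] if keep.any() else lam[:1]


# ---------------------------------------------------------------------------
# Liu moment matching
# ---------------------------------------------------------------------------

def liu_params(lam: np.ndarray):
    """(mu_Q, sigma_Q, df l, noncentrality d, mu_X, sigma_X)."""
    c1 = lam.sum()
    c2 = (lam ** 2).sum()
    c3 = (lam ** 3).sum()
    c4 = (lam ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        d = s1 * a ** 3 - a ** 2
        l = a ** 2 - 2.0 * d
    else:
        l = 1.0 / s2
        a = np.sqrt(l)
        d = 0.0
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    mu_x = l + d
    sigma_x = np.sqrt(2.0) * a
    return mu_q, sigma_q, l, d, mu_x, sigma_x


def liu_pvalue(q, lam) -> np.ndarray:
    lam = _clean_eigenvalues(lam)
    mu_q, sigma_q, l, d, mu_x, sigma_x = liu_params(lam)
    x = (np.asarray(q, dtype=float) - mu_q) / sigma_q * sigma_x + mu_x
    return ncx2.sf(x, df=l, nc=d) if d > 0 else chi2.sf(x, df=l)


def liu_quantile(p_tail, lam) -> float:
    """q with P(Q > q) = p_tail under the Liu approximation."""
    lam = _clean_eigenvalues(lam)
    mu_q, sigma_q, l, d, mu_x, sigma_x = liu_params(lam)
    x = ncx2.isf(p_tail, df=l, nc=d) if d > 0 else chi2.isf(p_tail, df=l)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


# ---------------------------------------------------------------------------
# Imhof / Davies inversion
# ---------------------------------------------------------------------------
#
# The Imhof integrand sin(theta(u)) / (u * rho(u)) oscillates at frequency
# ~q/2 and its envelope g(u) = 1/(u*rho(u)) decays like u^-(1+m/2). It is
# integrated by composite Gauss-Legendre on (0, U], with U chosen so the
# envelope is below tolerance relative to the oscillation frequency, and a
# first-order integration-by-parts correction g(U)cos(theta(U))/theta'(U)
# for the truncated tail (the residual is then O(g'(U)/omega^2)).

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_MAX_PANELS = 60_000


def _imhof_tail(q, lam, tol: float = 1e-9):
    """Tail probabilities for a vector of q sharing one eigenvalue set.

    One quadrature grid serves every q: the truncation point comes from
    the smallest positive q (widest tail), the panel density from the
    largest (fastest oscillation). Entries are NaN when the grid would
    exceed the panel cap (the caller then falls back to Liu).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.ones(q.shape)
    pos = q > 0.0
    if not pos.any():
        return out
    qp = q[pos]
    omega_min = 0.5 * qp.min()
    omega_max = 0.5 * qp.max()
    target = tol * max(omega_min, 1e-2)
    U = 1.0 / np.sqrt(lam.max())

    def envelope(u):
        return float(np.exp(-0.25 * np.log1p((lam * u) ** 2).sum()) / u)

    while envelope(U) > target and U < 1e9:
        U *= 2.0
    freq = omega_max + 0.5 * lam.sum()
    panel = 2.0 * (2.0 * np.pi / freq)
    n_panels = int(np.ceil(U / panel))
    if n_panels > _MAX_PANELS:
        out[pos] = np.nan
        return out
    edges = np.linspace(0.0, U, n_panels + 1)
    half = 0.5 * (edges[1] - edges[0])
    mid = 0.5 * (edges[1:] + edges[:-1])
    u = (mid[:, None] + half * _GL_NODES[None, :]).ravel()
    w = (half * np.broadcast_to(_GL_WEIGHTS, (n_panels, _GL_WEIGHTS.size))).ravel()
    lu = lam[:, None] * u[None, :]
    theta0 = 0.5 * np.arctan(lu).sum(axis=0)
    base = w * np.exp(-0.25 * np.log1p(lu * lu).sum(axis=0)) / u
    # tail-correction pieces at U
    luU = lam * U
    theta0U = 0.5 * np.arctan(luU).sum()
    gU = envelope(U)
    dtheta0U = 0.5 * (lam / (1.0 + luU * luU)).sum()

    res = np.empty(qp.shape)
    chunk = max(1, int(5e6) // max(u.size, 1))
    for k in range(0, qp.size, chunk):
        qc = qp[k:k + chunk, None]
        vals = (np.sin(theta0[None, :] - 0.5 * qc * u[None, :]) * base[None, :]).sum(axis=1)
        dthetaU = dtheta0U - 0.5 * qc[:, 0]
        thetaU = theta0U - 0.5 * qc[:, 0] * U
        vals = vals + np.where(np.abs(dthetaU) > 1e-12,
                               gU * np.cos(thetaU) / dthetaU, 0.0)
        res[k:k + chunk] = vals
    out[pos] = 0.5 + res / np.pi
    return out


def mixture_chi2_pvalue(eigenvalues, q, tol: float = 1e-9):
    """P(sum lambda_i chi2_1 > q) for scalar or vector q.

    Exact closed forms are used when all eigenvalues are equal; otherwise
    the Imhof integral with a Liu fallback when the numerical inversion
    leaves (0, 1) or fails to converge. Small negative eigenvalues
    (> -1e-8 relative) are clipped to zero; larger ones raise. ``tol``
    controls the quadrature truncation (absolute error scale).
    """
    lam = _clean_eigenvalues(eigenvalues)
    scalar = np.isscalar(q) or np.ndim(q) == 0
    qv = np.atleast_1d(np.asarray(q, dtype=float))
    if np.allclose(lam, lam[0], rtol=1e-12):
        p = chi2.sf(qv / lam[0], df=lam.size)
    else:
        try:
            p = _imhof_tail(qv, lam, tol=tol)
        except Exception:
            p = np.full(qv.shape, np.nan)
        bad = ~np.isfinite(p) | (p <= 1e-12) | (p >= 1.0)
        # tiny tails: Imhof's quadrature bottoms out near its abs tolerance
        if bad.any():
            p = np.where(bad, liu_pvalue(qv, lam), p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p[0]) if scalar else p
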