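"""Tail probabilities of (signed) mixtures of 1-df chi-square variables.

P(Q > q) for Q = sum_i lambda_i * chi2_1 is computed by Davies-style numerical
inversion of the characteristic function (Gil-Pelaez form, midpoint rule with
explicit aliasing and truncation error bounds). Eigenvalues may be negative
and may carry multiplicities, which makes the exact finite-sample null of
ratio-form statistics (quadratic form over estimated variance) available:
P(e'Ke/sigma_hat^2 > q) = P(e'(K - q I/(n-1))e > 0). Liu's moment-matching
approximation serves as a fallback when the inversion cannot certify the
requested accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["mixture_chi2_sf", "davies_sf", "liu_sf", "liu_params", "liu_quantile", "LiuParams"]

_N_CAP = 1 << 22  # hard cap on characteristic-function sample points per call


def _chernoff_bound(lam: np.ndarray, mult: np.ndarray, nc: np.ndarray, acc: float) -> float:
    """R with P(Q > R) <= acc via the moment-generating-function bound.

    Returns 0 when no positive eigenvalue exists (the sum is then <= 0 a.s.).
    """
    pos = lam > 0
    if not pos.any():
        return 0.0
    s = 0.45 / lam[pos].max()
    log_mgf = -0.5 * float(np.sum(mult * np.log1p(-2.0 * s * lam)))
    log_mgf += float(np.sum(s * lam * nc / (1.0 - 2.0 * s * lam)))
    return float(max((log_mgf - np.log(acc)) / s, 0.0))


def davies_sf(q: float, lam, mult=None, acc: float = 1e-9, nc=None) -> tuple[float, float]:
    """Upper tail of sum_i lambda_i chi2_{mult_i}(nc_i) by CF inversion.

    Returns (p, error_bound); the bound combines the aliasing tail, the
    truncation bound and discarded near-zero eigenvalues. A pure positive
    central single-component mixture is evaluated exactly via the scaled
    chi-square.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    mult = np.ones(lam.size) if mult is None else np.atleast_1d(np.asarray(mult, dtype=float))
    nc = np.zeros(lam.size) if nc is None else np.atleast_1d(np.asarray(nc, dtype=float))
    keep = lam != 0.0
    lam, mult, nc = lam[keep], mult[keep], nc[keep]
    if lam.size == 0:
        return (1.0 if q <= 0 else 0.0), 0.0
    scale = np.abs(lam).max()
    lam = lam / scale
    q = q / scale
    small = np.abs(lam) < 1e-7
    err_drop = 3.0 * float(np.sum(mult[small] * np.abs(lam[small]) * (1.0 + nc[small])))
    lam, mult, nc = lam[~small], mult[~small], nc[~small]
    if lam.size == 0:
        return (1.0 if q <= 0 else 0.0), err_drop
    if np.all(lam > 0):
        if q <= 0:
            return 1.0, err_drop
        if lam.size == 1:
            if nc[0] > 0:
                return float(stats.ncx2.sf(q / lam[0], df=mult[0], nc=nc[0])), err_drop
            return float(stats.chi2.sf(q / lam[0], df=mult[0])), err_drop
    elif np.all(lam < 0) and q >= 0:
        return 0.0, err_drop

    r_upper = _chernoff_bound(lam, mult, nc, acc)
    r_lower = _chernoff_bound(-lam, mult, nc, acc)
    period = abs(q) + r_upper + r_lower + 1e-3
    du = 2.0 * np.pi / period

    k_eff = float(mult.sum())
    log_prod_sqrt = 0.5 * float(np.sum(mult * np.log(np.abs(lam))))
    # truncation point: the smaller of the envelope-decay bound and (for q>0)
    # the oscillation (integration-by-parts) bound; the noncentral factor in
    # the integrand only speeds the decay, so the central bound is conservative
    log_u1 = (np.log(2.0 / (k_eff * acc)) - log_prod_sqrt) / (k_eff / 2.0)
    log_u = log_u1
    if q > 0:
        log_u2 = (np.log(2.0 / (q * acc)) - log_prod_sqrt) / (1.0 + k_eff / 2.0)
        log_u = min(log_u1, log_u2)
    U = float(np.exp(min(log_u, 40.0)))
    U = max(U, 20.0 * du)
    n_terms = int(min(np.ceil(U / du), _N_CAP))
    U = n_terms * du

    noncentral = bool(np.any(nc > 0))
    total = 0.0
    chunk = max(1, (1 << 20) // lam.size)
    for start in range(0, n_terms, chunk):
        j = np.arange(start, min(start + chunk, n_terms))
        u = (j + 0.5) * du
        lu = lam[None, :] * u[:, None]
        theta = 0.5 * (mult[None, :] * np.arctan(lu)).sum(axis=1) - 0.5 * q * u
        log_rho = 0.25 * (mult[None, :] * np.log1p(lu * lu)).sum(axis=1)
        if noncentral:
            denom = 1.0 + lu * lu
            theta += 0.5 * (nc[None, :] * lu / denom).sum(axis=1)
            log_rho += 0.5 * (nc[None, :] * (lu * lu) / denom).sum(axis=1)
        total += float(np.sum(np.sin(theta) * np.exp(-log_rho) / u))
    p = 0.5 + total * du / np.pi

    log_env = -(k_eff / 2.0) * np.log(U) - log_prod_sqrt
    err_trunc = (2.0 / k_eff) * float(np.exp(min(log_env, 40.0)))
    if q > 0:
        err_trunc = min(err_trunc, (2.0 / q) * float(np.exp(min(log_env - np.log(U), 40.0))))
    err = err_trunc + 2.0 * acc + err_drop
    return float(np.clip(p, 0.0, 1.0)), float(err)


def ratio_form_sf(q: float, nu, n: int, acc: float = 1e-9) -> tuple[float, float]:
    """Exact (Gaussian-errors) upper tail of Q = e'Ke / sigma_hat^2.

    ``nu`` are the nonzero eigenvalues of the centered kernel K (raw scale),
    ``sigma_hat^2 = e'e/(n-1)`` with e the centered response, and the event
    {Q > q} equals {sum_i (nu_i - c) chi2_1 - c chi2_{n-1-k} > 0}, c = q/(n-1).
    The result is free of the unknown error variance.
    """
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    k = nu.size
    if n - 1 - k < 0:
        raise ValueError("need n - 1 >= number of kernel eigenvalues")
    c = q / (n - 1)
    lam = np.concatenate([nu - c, [-c] if n - 1 - k > 0 else []])
    mult = np.concatenate([np.ones(k), [n - 1 - k] if n - 1 - k > 0 else []])
    return davies_sf(0.0, lam, mult, acc=acc)


@dataclass
class LiuParams:
    mu_q: float
    sigma_q: float
    mu_x: float
    sigma_x: float
    df: float
    ncp: float


def liu_params(lam) -> LiuParams:
    """Moment-matched noncentral chi-square parameters (kurtosis-matching
    variant used for the quadratic-form fallback and quantile inversion)."""
    lam = np.asarray(lam, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2 * ncp
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        ncp = 0.0
    return LiuParams(
        mu_q=float(c1),
        sigma_q=float(np.sqrt(2 * c2)),
        mu_x=float(df + ncp),
        sigma_x=float(np.sqrt(2) * a),
        df=float(df),
        ncp=float(ncp),
    )


def liu_sf(q: float, lam) -> float:
    """Liu et al. moment-matching upper tail for sum(lambda_i chi2_1)."""
    par = liu_params(lam)
    t = (q - par.mu_q) / par.sigma_q * par.sigma_x + par.mu_x
    if par.ncp > 0:
        return float(stats.ncx2.sf(t, df=par.df, nc=par.ncp))
    return float(stats.chi2.sf(t, df=par.df))


def liu_quantile(p_upper: float, lam) -> float:
    """Quantile q with P(Q > q) = p_upper under the Liu approximation."""
    par = liu_params(lam)
    if par.ncp > 0:
        x = stats.ncx2.isf(p_upper, df=par.df, nc=par.ncp)
    else:
        x = stats.chi2.isf(p_upper, df=par.df)
    return float((x - par.mu_x) / par.sigma_x * par.sigma_q + par.mu_q)


def mixture_chi2_sf(q: float, lam, acc: float = 1e-9) -> tuple[float, str]:
    """P(Q > q), positive mixture, with automatic Liu fallback;
    returns (p, 'davies' | 'liu')."""
    lam = np.asarray(lam, dtype=float)
    p, err = davies_sf(q, lam, acc=acc)
    if np.isfinite(p) and p > max(10.0 * err, acc):
        return float(p), "davies"
    return liu_sf(q, lam), "liu"
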