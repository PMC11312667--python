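"""Gene-based rare-variant association on Martingale-residual phenotypes.

The burden test collapses a gene/class variant set to a binary carrier
indicator (G_i = 1 iff any member dosage > 0) and regresses the residual on
it. SKAT keeps the per-variant genotypes, weighting by Beta(MAF; 1, 25), and
refers its quadratic form to a mixture of chi-squares. SKAT-O combines the
two over a grid of mixing weights rho; its min-p omnibus is evaluated
exactly as a two-dimensional event of the Gaussian score vector (squared
norm vs squared burden projection). Carrier-level follow-up per variant
runs a covariate-adjusted Cox model for every variant with minor allele
count >= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix
from .quadform import davies_sf, liu_quantile, mixture_chi2_sf, ratio_form_sf
from .survival import cox_carrier_hr
from .variant_classes import GeneVariantSet

logger = logging.getLogger(__name__)

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


#: Gauss-Legendre rule on [-1, 1] applied per smooth segment of the SKAT-O
#: omnibus integrand
_GL_SEGMENT = np.polynomial.legendre.leggauss(48)


def beta_maf_weights(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1,25) density weights up-weighting the rarest variants."""
    maf = np.asarray(maf, dtype=float)
    return stats.beta.pdf(np.clip(maf, 1e-12, 1 - 1e-12), a, b)


def collapse(G_sub: np.ndarray) -> np.ndarray:
    """Binary carrier indicator: 1 iff the subject's dosage sum over the
    gene/class variants is > 0. Missing dosages count as non-carrier."""
    G_sub = np.asarray(G_sub, dtype=float)
    if G_sub.ndim == 1:
        G_sub = G_sub[:, None]
    if G_sub.shape[1] == 0:
        raise ValueError("empty variant set")
    if np.isnan(G_sub).any():
        logger.debug("missing dosages treated as 0 in carrier collapse")
    return (np.nan_to_num(G_sub) > 0).any(axis=1).astype(int)


def burden_test(residuals, carrier) -> tuple[float, float, float]:
    """OLS of Martingale residual on the carrier indicator with intercept;
    returns (beta, se, two-sided p)."""
    y = np.asarray(residuals, dtype=float)
    c = np.asarray(carrier, dtype=float)
    n = y.size
    n_car = c.sum()
    if n_car == 0 or n_car == n:
        raise ValueError("carrier indicator is constant (all or no subjects carry)")
    cx = c - c.mean()
    sxx = float(cx @ cx)
    beta = float(cx @ y) / sxx
    resid = y - y.mean() - beta * cx
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return beta, se, max(p, np.finfo(float).tiny)


def _null_pieces(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Intercept-only null model: centered residuals and sigma^2 estimate."""
    e = y - y.mean()
    sigma2 = float(e @ e) / (y.size - 1)
    if sigma2 <= 0:
        raise ValueError("residual variance must be positive")
    return e, sigma2


def _raw_kernel(G_sub: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """A = (P0 G W)'(P0 G W) — raw-scale Gram matrix of the centered,
    weighted genotypes (the null score covariance up to sigma^2)."""
    Zc = (G_sub - G_sub.mean(axis=0)) * weights
    return Zc.T @ Zc


def _positive_eigvals(A: np.ndarray) -> np.ndarray:
    nu = np.linalg.eigvalsh(A)
    return nu[nu > 1e-10 * max(nu.max(initial=0.0), 1.0)]


@dataclass
class SkatResult:
    Q: float
    p: float
    method: str


def skat_test(residuals, G_sub, weights=None, maf=None, null: str = "exact") -> SkatResult:
    """Variance-component (SKAT) test with Beta(1,25) MAF weights.

    Q = ||W G' (y - ybar)||^2 / sigma_hat^2 referred to its null distribution
    by Davies-style CF inversion. ``null="exact"`` (default) uses the exact
    finite-sample distribution of the variance-standardized quadratic form
    under Gaussian errors (a signed chi-square mixture, free of sigma);
    ``null="asymptotic"`` uses the classic sum(lambda chi2_1) reference with
    Liu fallback.
    """
    y = np.asarray(residuals, dtype=float)
    G_sub = np.nan_to_num(np.asarray(G_sub, dtype=float))
    if G_sub.ndim == 1:
        G_sub = G_sub[:, None]
    if weights is None:
        if maf is None:
            maf = G_sub.mean(axis=0) / 2.0
        weights = beta_maf_weights(maf)
    weights = np.asarray(weights, dtype=float)
    e, sigma2 = _null_pieces(y)
    n = y.size
    score = weights * (G_sub.T @ e)
    Q = float(score @ score) / sigma2
    nu = _positive_eigvals(_raw_kernel(G_sub, weights))
    if nu.size == 0:
        logger.warning("zero-variance SKAT kernel; p set to 1")
        return SkatResult(Q=Q, p=1.0, method="degenerate")
    if null == "exact":
        p, err = ratio_form_sf(Q, nu, n)
        if np.isfinite(p) and err < max(1e-6, 0.05 * max(p, 1e-12)):
            return SkatResult(Q=Q, p=max(p, np.finfo(float).tiny), method="davies-exact")
        logger.debug("exact null not certified (err=%g); asymptotic fallback", err)
    p, method = mixture_chi2_sf(Q, nu)
    return SkatResult(Q=Q, p=max(p, np.finfo(float).tiny), method=method)


@dataclass
class SkatOResult:
    p: float
    rho_min: float
    rho_grid: tuple
    p_rho: dict
    Q_rho: dict
    method: str


def _rho_sqrt(rho: float, k: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    a = np.sqrt(1.0 - rho + k * rho)
    b = np.sqrt(1.0 - rho)
    P1 = np.full((k, k), 1.0 / k)
    return a * P1 + b * (np.eye(k) - P1)


def skato_test(residuals, G_sub, weights=None, maf=None,
               rho_grid=DEFAULT_RHO_GRID, null: str = "exact") -> SkatOResult:
    """SKAT-O: Q_rho = (1-rho) Q_SKAT + rho Q_burden over the rho grid, with
    the min-p omnibus P(min_rho p_rho <= T) computed by conditioning on the
    burden component of the Gaussian score vector.

    Per-rho p-values use the exact finite-sample ratio-form null by default
    (``null="asymptotic"`` selects the classic mixture reference). A
    single-point grid returns that component's p directly (rho = 0 is SKAT,
    rho = 1 the weighted-sum burden score test). Degenerate geometry or
    integration failure falls back to Bonferroni over the grid (logged).
    """
    y = np.asarray(residuals, dtype=float)
    G_sub = np.nan_to_num(np.asarray(G_sub, dtype=float))
    if G_sub.ndim == 1:
        G_sub = G_sub[:, None]
    k = G_sub.shape[1]
    n = y.size
    if weights is None:
        if maf is None:
            maf = G_sub.mean(axis=0) / 2.0
        weights = beta_maf_weights(maf)
    weights = np.asarray(weights, dtype=float)
    rho_grid = tuple(float(r) for r in rho_grid)
    e, sigma2 = _null_pieces(y)
    score = weights * (G_sub.T @ e)
    Q_skat = float(score @ score) / sigma2
    Q_burden = float(score.sum()) ** 2 / sigma2
    A_raw = _raw_kernel(G_sub, weights)

    p_rho: dict[float, float] = {}
    Q_rho: dict[float, float] = {}
    lam_rho: dict[float, np.ndarray] = {}
    method = "davies-exact" if null == "exact" else "davies"
    for rho in rho_grid:
        Q = (1.0 - rho) * Q_skat + rho * Q_burden
        S = _rho_sqrt(rho, k)
        nu = _positive_eigvals(S @ A_raw @ S)
        if nu.size == 0:
            logger.warning("zero-variance kernel at rho=%g; p set to 1", rho)
            p_rho[rho], Q_rho[rho] = 1.0, Q
            lam_rho[rho] = np.array([1.0])
            continue
        if null == "exact":
            p, err = ratio_form_sf(Q, nu, n)
            if not (np.isfinite(p) and err < max(1e-6, 0.05 * max(p, 1e-12))):
                p, m = mixture_chi2_sf(Q, nu)
                method = m
        else:
            p, m = mixture_chi2_sf(Q, nu)
            if m == "liu":
                method = "liu"
        p_rho[rho] = max(p, np.finfo(float).tiny)
        Q_rho[rho] = Q
        lam_rho[rho] = nu

    T = min(p_rho.values())
    rho_min = min(p_rho, key=p_rho.get)
    if len(rho_grid) == 1:
        return SkatOResult(p=p_rho[rho_grid[0]], rho_min=rho_grid[0], rho_grid=rho_grid,
                           p_rho=p_rho, Q_rho=Q_rho, method=method)

    # Omnibus: P(min_rho p_rho <= T), computed exactly for a Gaussian score
    # vector S ~ N(0, A). Q_burden is the squared burden component x = 1'S
    # (up to scale) and Q_skat | x is a noncentral chi-square mixture, so the
    # union over rho of {Q_rho > q_rho(T)} reduces to a one-dimensional
    # integral over x of a Davies tail probability.
    varb = float(A_raw.sum())  # null variance of the burden score component
    if varb <= 0 or k == 1:
        # every grid statistic is affine in one underlying variable: the
        # omnibus is the single shared test
        return SkatOResult(p=T, rho_min=rho_min, rho_grid=rho_grid,
                           p_rho=p_rho, Q_rho=Q_rho, method=method)

    def _bonferroni(reason: str) -> SkatOResult:
        logger.warning("SKAT-O omnibus %s; Bonferroni over the rho grid", reason)
        return SkatOResult(p=min(1.0, T * len(rho_grid)), rho_min=rho_min, rho_grid=rho_grid,
                           p_rho=p_rho, Q_rho=Q_rho, method="bonferroni")

    # thresholds on the Gaussian-model scale: keeps every marginal event at
    # probability T under the same (Gaussian) law that supplies the joint
    # dependence, so the only omnibus error is in the copula
    try:
        q_thr = {r: _gauss_quantile(T, lam_rho[r]) for r in rho_grid}
    except Exception:
        return _bonferroni("threshold inversion failed")

    Ac = A_raw.sum(axis=1)
    B = A_raw - np.outer(Ac, Ac) / varb
    lamB, V = np.linalg.eigh(B)
    keepB = lamB > 1e-10 * max(lamB.max(initial=0.0), 1.0)
    lamB_k = lamB[keepB]
    mu_dir = Ac / varb  # E[S | x] = mu_dir * x
    m_dir = V[:, keepB].T @ mu_dir
    const_dir = max(float(mu_dir @ mu_dir - m_dir @ m_dir), 0.0)
    finite = [(r, q_thr[r]) for r in rho_grid if r < 1.0]
    a_coef = np.array([q / (1.0 - r) for r, q in finite])
    b_coef = np.array([r / (1.0 - r) for r, _ in finite])
    x2_cap = min((q_thr[r] for r in rho_grid if r >= 1.0), default=np.inf)
    z_cap = min(float(np.sqrt(x2_cap / varb)) if np.isfinite(x2_cap) else 8.5, 8.5)

    def keep_prob(z: float) -> float:
        """P(no rho < 1 statistic exceeds its threshold | burden z-score)."""
        x2 = z * z * varb
        t_min = float(np.min(a_coef - b_coef * x2)) if a_coef.size else np.inf
        rem = t_min - const_dir * x2
        if lamB_k.size == 0:
            return 1.0 if rem >= 0 else 0.0
        if not np.isfinite(rem):
            return 1.0
        shift = m_dir * z * np.sqrt(varb) / np.sqrt(lamB_k)
        if lamB_k.size <= 2:
            return _small_noncentral_cdf(rem, lamB_k, shift)
        sf, _ = davies_sf(rem, lamB_k, nc=shift**2, acc=1e-8)
        return 1.0 - sf

    # the min over rho switches linearly in x^2: split at the lower-envelope
    # crossing points (grid-located, analytically refined)
    breaks = {0.0, z_cap}
    if a_coef.size > 1 and z_cap > 0:
        z_grid = np.linspace(0.0, z_cap, 513)
        which = np.argmin(a_coef[None, :] - b_coef[None, :] * (varb * z_grid**2)[:, None], axis=1)
        for pos in np.flatnonzero(np.diff(which)):
            i, j = which[pos], which[pos + 1]
            db = b_coef[i] - b_coef[j]
            if db != 0.0:
                x2 = (a_coef[i] - a_coef[j]) / db
                if x2 > 0 and 0.0 < np.sqrt(x2 / varb) < z_cap:
                    breaks.add(float(np.sqrt(x2 / varb)))
    try:
        xg, wg = _GL_SEGMENT
        edges = sorted(breaks)
        integral = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
            for xnode, wnode in zip(xg, wg):
                z = mid + half * xnode
                integral += half * wnode * keep_prob(z) * 2.0 * np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        p_omni = 1.0 - integral
    except Exception:
        return _bonferroni("integration failed")
    # the omnibus cannot beat its best component nor exceed grid Bonferroni
    p_omni = float(np.clip(p_omni, T, min(1.0, T * len(rho_grid))))
    return SkatOResult(p=p_omni, rho_min=rho_min, rho_grid=rho_grid,
                       p_rho=p_rho, Q_rho=Q_rho, method=method)


_GL_INNER = np.polynomial.legendre.leggauss(160)


def _small_noncentral_cdf(t: float, lam: np.ndarray, shift: np.ndarray) -> float:
    """P(sum_i lam_i (xi_i + shift_i)^2 <= t) for one or two components,
    xi_i independent standard normal — direct Gaussian quadrature."""
    from scipy.special import ndtr

    if t <= 0:
        return 0.0
    if lam.size == 1:
        r = np.sqrt(t / lam[0])
        return float(ndtr(r - shift[0]) - ndtr(-r - shift[0]))
    # order so the outer integral runs over the larger-lambda component
    i, j = (0, 1) if lam[0] >= lam[1] else (1, 0)
    r1 = np.sqrt(t / lam[i])
    xg, wg = _GL_INNER
    xi = -shift[i] + r1 * xg  # xi_i + shift_i in (-r1, r1)
    s = t - lam[i] * (xi + shift[i]) ** 2
    r2 = np.sqrt(np.maximum(s, 0.0) / lam[j])
    inner = ndtr(r2 - shift[j]) - ndtr(-r2 - shift[j])
    dens = np.exp(-0.5 * xi * xi) / np.sqrt(2.0 * np.pi)
    return float(np.sum(wg * r1 * inner * dens))


def _gauss_quantile(p_upper: float, lam) -> float:
    """Quantile of sum(lam_i chi2_1) at upper-tail probability ``p_upper``,
    by root-finding on the Davies tail from a Liu starting point."""
    from scipy.optimize import brentq

    q0 = max(liu_quantile(p_upper, lam), 1e-12)

    def f(q):
        return davies_sf(q, lam, acc=1e-9)[0] - p_upper

    lo, hi = q0 / 2.0, q0 * 2.0
    for _ in range(60):
        if f(lo) > 0:
            break
        lo /= 2.0
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-12 * max(q0, 1.0), rtol=1e-10))


@dataclass
class GeneTestResult:
    gene: str
    variant_class: str
    n_variants: int
    n_carriers: int
    burden_beta: float
    burden_se: float
    burden_p: float
    skat_Q: float
    skat_p: float
    skato_p: float
    skato_rho_min: float
    skato_rho_grid: tuple = field(default=DEFAULT_RHO_GRID)
    method: str = "davies"


def run_gene_tests(residuals, G: GenotypeMatrix, gene_sets: list[GeneVariantSet]) -> list[GeneTestResult]:
    """Burden + SKAT + SKAT-O for every gene/class variant set."""
    out = []
    for gs in gene_sets:
        G_sub = gs.dosage(G)
        maf = G.maf[gs.variant_idx]
        carrier = collapse(G_sub)
        b_beta, b_se, b_p = burden_test(residuals, carrier)
        sk = skat_test(residuals, G_sub, maf=maf)
        so = skato_test(residuals, G_sub, maf=maf)
        out.append(
            GeneTestResult(
                gene=gs.gene,
                variant_class=gs.variant_class.value,
                n_variants=gs.n_variants,
                n_carriers=gs.n_carriers,
                burden_beta=b_beta,
                burden_se=b_se,
                burden_p=b_p,
                skat_Q=sk.Q,
                skat_p=sk.p,
                skato_p=so.p,
                skato_rho_min=so.rho_min,
                skato_rho_grid=so.rho_grid,
                method=f"{sk.method}/{so.method}",
            )
        )
    return out


def results_table(results: list[GeneTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "class": r.variant_class,
                "k": r.n_variants,
                "carriers": r.n_carriers,
                "burden_beta": r.burden_beta,
                "burden_p": r.burden_p,
                "skat_p": r.skat_p,
                "skato_p": r.skato_p,
                "method": r.method,
            }
            for r in results
        ]
    )


def gene_wide_threshold(n_genes_per_class, n_classes: int | None = None,
                        n_methods: int = 1, alpha: float = 0.05) -> float:
    """Bonferroni threshold over genes x variant classes x statistical methods.

    ``n_genes_per_class`` may be a per-class sequence of gene counts (summed)
    or a single count applied to every class.
    """
    if np.iterable(n_genes_per_class):
        counts = [int(c) for c in n_genes_per_class]
        if n_classes is not None and n_classes != len(counts):
            raise ValueError("n_classes inconsistent with the per-class counts")
        total = sum(counts) * n_methods
    else:
        total = int(n_genes_per_class) * (n_classes or 1) * n_methods
    if total <= 0:
        raise ValueError("total number of tests must be positive")
    return alpha / total


def per_variant_cox(
    cohort: pd.DataFrame,
    G_sub: np.ndarray,
    variant_ids,
    covariates: list[str] | None = None,
    min_mac: int = 3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Carrier-status Cox regression per variant (complete cases), restricted
    to variants with MAC >= ``min_mac``; Bonferroni threshold alpha / n_tested."""
    G_sub = np.asarray(G_sub, dtype=float)
    if G_sub.ndim == 1:
        G_sub = G_sub[:, None]
    variant_ids = np.asarray(variant_ids)
    rows = []
    for j in range(G_sub.shape[1]):
        g = G_sub[:, j]
        obs = ~np.isnan(g)
        mac = float(np.nansum(g))
        if mac < min_mac:
            continue
        sub = cohort.loc[obs].reset_index(drop=True)
        try:
            res = cox_carrier_hr(sub, (g[obs] > 0).astype(int), covariates)
        except Exception as exc:  # separation / no events in carriers
            logger.warning("per-variant Cox failed for %s: %s", variant_ids[j], exc)
            rows.append({"variant_id": variant_ids[j], "mac": int(mac), "hr": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan})
            continue
        rows.append({"variant_id": variant_ids[j], "mac": int(mac), "hr": res["hr"],
                     "ci_lower": res["ci"][0], "ci_upper": res["ci"][1], "p": res["p"]})
    table = pd.DataFrame(rows, columns=["variant_id", "mac", "hr", "ci_lower", "ci_upper", "p"])
    n_tested = len(table)
    threshold = alpha / n_tested if n_tested else float("nan")
    return table, threshold
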