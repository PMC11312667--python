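"""Cox proportional-hazards machinery on the age scale.

The hazard model is H(t | z) = H0(t) * exp(z'beta). Fitting maximizes the Cox
partial likelihood by Newton-Raphson with step-halving; the baseline cumulative
hazard H0 is the Breslow step-function estimator; Martingale residuals are
M_i = delta_i - H0(t_i) * exp(z_i'beta) and serve downstream as a continuous
GWAS phenotype. Time is age in years with no delayed entry.

Kaplan-Meier curves and the log-rank test delegate to lifelines; the Cox score
test at beta = 0 is computed from the same partial-likelihood quantities and
coincides with the log-rank chi-square when there are no ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (monotone likelihood / separation)."""


@dataclass
class CoxFit:
    beta_hat: np.ndarray
    cov_beta: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    loglik: float
    n_events: int
    ties_method: str
    covariate_names: list[str]
    n_iter: int = 0

    def cumhaz_at(self, times) -> np.ndarray:
        """Right-continuous H0 evaluated at arbitrary times.

        Times beyond the last baseline step reuse the final value.
        """
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.baseline_times, times, side="right") - 1
        out = np.zeros_like(times, dtype=float)
        inside = idx >= 0
        out[inside] = self.baseline_cumhaz[idx[inside]]
        if self.baseline_times.size and np.any(times > self.baseline_times[-1]):
            logger.debug("times beyond fitted range use the last baseline step")
        return out

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta_hat)

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


@dataclass
class SurvCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    group: object


def _as_arrays(durations, events, Z):
    t = np.asarray(durations, dtype=float)
    d = np.asarray(events, dtype=int)
    if Z is None or (hasattr(Z, "shape") and np.size(Z) == 0):
        Z = np.empty((t.size, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if t.size != d.size or Z.shape[0] != t.size:
        raise ValueError("durations, events and covariates must align")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    return t, d, Z


def _loglik_grad_hess(beta, t, d, Z, ties):
    """Partial log-likelihood, score and observed information at beta.

    Expects data sorted by ascending time. Risk-set aggregates are reverse
    cumulative sums; tied event times use Efron's or Breslow's correction.
    """
    n, p = Z.shape
    eta = Z @ beta
    eta -= eta.max() if n else 0.0  # guard overflow; constant shifts cancel
    theta = np.exp(eta)
    thZ = theta[:, None] * Z
    thZZ = thZ[:, :, None] * Z[:, None, :]
    # reverse cumulative sums: S*(i) aggregates subjects with time >= t_i
    S0 = np.cumsum(theta[::-1])[::-1]
    S1 = np.cumsum(thZ[::-1], axis=0)[::-1]
    S2 = np.cumsum(thZZ[::-1], axis=0)[::-1]

    ev = np.flatnonzero(d == 1)
    # group tied event times
    ev_t = t[ev]
    first = np.ones(ev.size, dtype=bool)
    first[1:] = ev_t[1:] != ev_t[:-1]
    grp_start = np.flatnonzero(first)
    grp_sizes = np.diff(np.append(grp_start, ev.size))

    ll = float(np.sum(eta[ev]))
    grad = Z[ev].sum(axis=0)
    hess = np.zeros((p, p))
    if ties == "breslow" and np.all(grp_sizes == 1):
        i0 = ev
        s0 = S0[i0]
        r1 = S1[i0] / s0[:, None]
        ll -= float(np.sum(np.log(s0)))
        grad -= r1.sum(axis=0)
        hess = np.einsum("ijk,i->jk", S2[i0], 1.0 / s0) - r1.T @ r1
    else:
        for gs, gn in zip(grp_start, grp_sizes):
            members = ev[gs : gs + gn]
            i0 = members[0]
            s0, s1, s2 = S0[i0], S1[i0], S2[i0]
            if ties == "breslow" or gn == 1:
                for _ in range(gn):
                    r1 = s1 / s0
                    ll -= np.log(s0)
                    grad -= r1
                    hess += s2 / s0 - np.outer(r1, r1)
            elif ties == "efron":
                td0 = theta[members].sum()
                td1 = thZ[members].sum(axis=0)
                td2 = thZZ[members].sum(axis=0)
                for l in range(gn):
                    f = l / gn
                    a0 = s0 - f * td0
                    a1 = s1 - f * td1
                    a2 = s2 - f * td2
                    r1 = a1 / a0
                    ll -= np.log(a0)
                    grad -= r1
                    hess += a2 / a0 - np.outer(r1, r1)
            else:
                raise ValueError(f"unknown ties method: {ties!r}")
    return ll, grad, hess


def fit_cox(
    durations,
    events,
    covariates=None,
    *,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
    covariate_names: list[str] | None = None,
) -> CoxFit:
    """Fit the Cox model by Newton-Raphson; return coefficients, covariance
    from the inverse observed information, and the Breslow baseline H0.

    With no covariates the baseline reduces to the Nelson-Aalen estimator.
    Raises :class:`ConvergenceError` on monotone likelihood (separation) and
    ``ValueError`` when there are no events.
    """
    t, d, Z = _as_arrays(durations, events, covariates)
    if d.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    order = np.argsort(t, kind="stable")
    t_s, d_s, Z_s = t[order], d[order], Z[order]
    p = Z.shape[1]
    if p and np.linalg.matrix_rank(np.column_stack([np.ones(t.size), Z])) < p + 1:
        raise ValueError("covariates are collinear (rank-deficient design)")
    names = covariate_names or [f"x{j}" for j in range(p)]

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, t_s, d_s, Z_s, ties)
    n_iter = 0
    if p:
        for n_iter in range(1, max_iter + 1):
            gnorm = float(np.linalg.norm(grad, ord=np.inf))
            if gnorm < tol:
                break
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix at iteration {n_iter}") from exc
            # step-halving keeps the partial likelihood nondecreasing
            # (up to float accumulation noise, which scales with |loglik|)
            noise = 1e-9 * max(1.0, abs(ll))
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, grad_new, hess_new = _loglik_grad_hess(cand, t_s, d_s, Z_s, ties)
                if ll_new >= ll - noise:
                    break
                scale /= 2.0
            else:
                raise ConvergenceError("step-halving failed to improve the partial likelihood")
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        else:
            raise ConvergenceError(
                "Newton-Raphson did not converge in "
                f"{max_iter} iterations (|grad|={np.linalg.norm(grad, ord=np.inf):.3g}); "
                "monotone likelihood / separation is a likely cause"
            )
        if np.any(np.abs(beta) > 30):
            raise ConvergenceError("coefficients diverged; separation is a likely cause")
    try:
        cov = np.linalg.inv(hess) if p else np.empty((0, 0))
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information at the optimum; separation is a likely cause") from exc

    # Breslow baseline cumulative hazard at the fitted beta
    theta = np.exp(Z_s @ beta) if p else np.ones(t.size)
    S0 = np.cumsum(theta[::-1])[::-1]
    ev = np.flatnonzero(d_s == 1)
    ev_times, first_idx = np.unique(t_s[ev], return_index=True)
    d_counts = np.bincount(np.searchsorted(ev_times, t_s[ev]))
    # S0 at the first index of each unique event time (data sorted ascending)
    s0_at = S0[np.searchsorted(t_s, ev_times, side="left")]
    increments = d_counts / s0_at
    H0 = np.cumsum(increments)

    return CoxFit(
        beta_hat=beta,
        cov_beta=cov,
        baseline_times=ev_times,
        baseline_cumhaz=H0,
        loglik=float(ll),
        n_events=int(d.sum()),
        ties_method=ties,
        covariate_names=names,
        n_iter=n_iter,
    )


def cox_score_test(durations, events, covariates, *, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of beta = 0; equals the log-rank chi-square for a
    binary group covariate when there are no ties."""
    t, d, Z = _as_arrays(durations, events, covariates)
    order = np.argsort(t, kind="stable")
    _, grad, hess = _loglik_grad_hess(np.zeros(Z.shape[1]), t[order], d[order], Z[order], ties)
    chi2 = float(grad @ np.linalg.solve(hess, grad))
    p = float(stats.chi2.sf(chi2, df=Z.shape[1]))
    return chi2, p


def martingale_residuals(fit: CoxFit, durations, events, covariates=None) -> np.ndarray:
    """M_i = delta_i - H0(t_i) * exp(z_i' beta), H0 evaluated right-continuously
    at each subject's own event/censoring time."""
    t, d, Z = _as_arrays(durations, events, covariates)
    if Z.shape[1] != fit.beta_hat.size:
        raise ValueError("covariate dimension does not match the fit")
    risk = np.exp(Z @ fit.beta_hat) if fit.beta_hat.size else np.ones(t.size)
    return d - fit.cumhaz_at(t) * risk


def cohort_null_residuals(cohort: pd.DataFrame, covariates: list[str] | None = None, *, ties: str = "breslow"):
    """Fit the genotype-free null Cox model (sex + PCs by default) on a cohort
    table and return (fit, Martingale residuals aligned to cohort rows)."""
    if covariates is None:
        covariates = ["sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
    Z = cohort[covariates].to_numpy(dtype=float) if covariates else None
    fit = fit_cox(cohort["age"], cohort["event"], Z, ties=ties, covariate_names=list(covariates))
    resid = martingale_residuals(fit, cohort["age"], cohort["event"], Z)
    return fit, resid


def kaplan_meier(durations, events, groups=None) -> list[SurvCurve]:
    """Product-limit survival curves (one per group) with at-risk counts."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(durations, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.zeros(t.size) if groups is None else np.asarray(groups)
    curves = []
    for label in pd.unique(g):
        mask = g == label
        if not mask.any():
            raise ValueError(f"empty group: {label}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], d[mask])
        tab = kmf.event_table
        curves.append(
            SurvCurve(
                times=kmf.survival_function_.index.to_numpy(dtype=float),
                survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
                at_risk=tab["at_risk"].to_numpy(),
                group=label,
            )
        )
    return curves


def logrank_test(durations, events, groups) -> tuple[float, float]:
    """Log-rank chi-square test (groups - 1 df) across >= 2 groups."""
    from lifelines.statistics import multivariate_logrank_test

    t = np.asarray(durations, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group in log-rank test")
    res = multivariate_logrank_test(t, g, d)
    return float(res.test_statistic), float(res.p_value)


def cox_carrier_hr(
    cohort: pd.DataFrame,
    carrier_status,
    covariates: list[str] | None = None,
    *,
    ties: str = "efron",
) -> dict:
    """Hazard ratio for carrier status adjusted for covariates, with Wald 95% CI.

    Mirrors the survival characterization of gene-burden carriers: a Cox model
    with the binary carrier indicator plus sex and the first five PCs.
    """
    carrier = np.asarray(carrier_status, dtype=float)
    if carrier.sum() == 0:
        raise ValueError("no carriers")
    if covariates is None:
        covariates = ["sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
    cols = [carrier] + [cohort[c].to_numpy(dtype=float) for c in covariates]
    Z = np.column_stack(cols)
    fit = fit_cox(
        cohort["age"], cohort["event"], Z, ties=ties, covariate_names=["carrier"] + list(covariates)
    )
    beta = fit.beta_hat[0]
    se = fit.se_beta()[0]
    z = beta / se
    with np.errstate(over="ignore"):  # an unbounded upper CI is meaningful
        ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    return {
        "hr": float(np.exp(beta)),
        "ci": ci,
        "p": float(2 * stats.norm.sf(abs(z))),
        "beta": float(beta),
        "se": float(se),
        "fit": fit,
    }


def survcurve_table(curves: list[SurvCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append({"time": t, "survival": s, "at_risk": r, "group": c.group})
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "group"])
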