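"""Phenome-wide association of carrier status and cause-of-death enrichment.

Binary phenotypes are tested by logistic regression, continuous ones by OLS,
each with age, sex and the first five PCs as covariates and per-phenotype
complete cases. Phenotypes with fewer than 100 cases (binary) or fewer than
100 non-missing values (continuous) are removed, as are phenotypes whose ICD
code prefix falls in excluded chapter ranges. The phenome-wide Bonferroni
threshold is alpha over the number of phenotypes tested (0.05/1,670 in a
full-phenome run, displayed truncated to 2.9e-5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: ICD-10 chapters XIX-XXII: injuries/external causes/health-service contacts/special codes
DEFAULT_EXCLUDED_PREFIXES = ("S", "T", "V", "W", "X", "Y", "Z", "U")

DEFAULT_COVARIATES = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]


def filter_phenotypes(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    min_cases: int = 100,
    excluded_prefixes: tuple[str, ...] = DEFAULT_EXCLUDED_PREFIXES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop binary phenotypes with < ``min_cases`` cases, continuous ones with
    < ``min_cases`` non-missing values, and code prefixes in excluded chapters.

    Idempotent: filtering an already-filtered matrix is a no-op.
    """
    keep = []
    for _, row in meta.iterrows():
        pid = row["phenotype_id"]
        if pid not in values.columns:
            continue
        code = str(row.get("code", "") or "")
        if code and code[0].upper() in excluded_prefixes:
            continue
        col = values[pid]
        if row["kind"] == "binary":
            if (col == 1).sum() < min_cases:
                continue
        else:
            if col.notna().sum() < min_cases:
                continue
        keep.append(pid)
    meta_out = meta.loc[meta["phenotype_id"].isin(keep)].reset_index(drop=True)
    return values[keep], meta_out


@dataclass
class PhewasResult:
    phenotype_id: str
    kind: str
    effect: float  # OR for binary, beta for continuous
    p: float
    n: int
    n_cases: int | None
    model: str


def _fit_logistic(y, X):
    import statsmodels.api as sm

    model = sm.Logit(y, X)
    return model.fit(disp=0, maxiter=100)


def run_phewas(
    carrier,
    values: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> list[PhewasResult]:
    """Carrier-status PheWAS over a filtered phenotype matrix.

    ``covariates`` is a subjects-aligned DataFrame (age, sex, pc1..pc5 by
    default when those columns exist). Perfect separation or non-convergence
    yields an NA-flagged result with a diagnostic, not an exception.
    """
    import statsmodels.api as sm

    carrier = np.asarray(carrier, dtype=float)
    if carrier.size != len(values):
        raise ValueError("carrier vector must align with the phenotype matrix rows")
    if covariates is None:
        covariates = pd.DataFrame(index=values.index)
    cov = covariates.reset_index(drop=True).astype(float)
    results: list[PhewasResult] = []
    for _, row in meta.iterrows():
        pid = row["phenotype_id"]
        kind = row["kind"]
        y = values[pid].to_numpy(dtype=float)
        ok = np.isfinite(y)
        for c in cov.columns:
            ok &= np.isfinite(cov[c].to_numpy())
        yk = y[ok]
        X = np.column_stack([np.ones(ok.sum()), carrier[ok]] + [cov[c].to_numpy()[ok] for c in cov.columns])
        n_cases = int((yk == 1).sum()) if kind == "binary" else None
        if np.nanstd(yk) == 0:
            logger.warning("phenotype %s constant; NA result", pid)
            results.append(PhewasResult(pid, kind, math.nan, math.nan, int(ok.sum()), n_cases, "na"))
            continue
        try:
            if kind == "binary":
                fit = _fit_logistic(yk, X)
                if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse[1]):
                    raise ValueError("logistic fit did not converge (possible separation)")
                results.append(
                    PhewasResult(pid, kind, float(np.exp(fit.params[1])), float(fit.pvalues[1]),
                                 int(ok.sum()), n_cases, "logistic")
                )
            else:
                fit = sm.OLS(yk, X).fit()
                results.append(
                    PhewasResult(pid, kind, float(fit.params[1]), float(fit.pvalues[1]),
                                 int(ok.sum()), None, "linear")
                )
        except Exception as exc:
            logger.warning("phenotype %s: %s; NA result", pid, exc)
            results.append(PhewasResult(pid, kind, math.nan, math.nan, int(ok.sum()), n_cases, "na"))
    return results


def phewas_table(results: list[PhewasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"phenotype_id": r.phenotype_id, "kind": r.kind, "effect": r.effect,
             "p": r.p, "n": r.n, "n_cases": r.n_cases, "model": r.model}
            for r in results
        ]
    )


def truncate_sig(x: float, digits: int = 2) -> float:
    """Truncate (not round) to ``digits`` significant figures, display style."""
    if x == 0 or not np.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exp - digits + 1)
    return math.floor(x / factor) * factor


def phewas_threshold(n_phenotypes: int, alpha: float = 0.05) -> tuple[float, float]:
    """(full-precision alpha/n, 2-significant-figure truncated display value).

    Comparisons use the full-precision value; the display value reproduces
    how such thresholds are conventionally printed (0.05/1,670 -> 2.9e-5).
    """
    if n_phenotypes <= 0:
        raise ValueError("n_phenotypes must be positive")
    full = alpha / n_phenotypes
    return full, truncate_sig(full, 2)


def carrier_enrichment(carrier, category_labels) -> pd.DataFrame:
    """Per-category 2x2 chi-square (1 df, no continuity correction) of carrier
    status for in-category versus all other subjects.

    Mirrors the cause-of-death carrier-enrichment analysis: for each primary
    cause, is the carrier proportion among those deaths different from the
    rest of the cohort?
    """
    carrier = np.asarray(carrier).astype(int)
    labels = np.asarray(category_labels)
    if carrier.size != labels.size:
        raise ValueError("carrier and category labels must align")
    prev = carrier.mean()
    if not 0 < prev < 1:
        raise ValueError("carrier prevalence must be strictly between 0 and 1")
    cats = pd.unique(labels)
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    rows = []
    for cat in cats:
        inside = labels == cat
        table = np.array(
            [
                [int((carrier & inside).sum()), int((~carrier.astype(bool) & inside).sum())],
                [int((carrier & ~inside).sum()), int(((~carrier.astype(bool)) & ~inside).sum())],
            ]
        )
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < 5).any():
            logger.warning("category %r has expected cell counts < 5", cat)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"category": cat, "n": int(inside.sum()),
                     "carrier_freq": float(carrier[inside].mean()), "chi2": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)
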