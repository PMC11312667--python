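"""Common-variant QC and Martingale-residual association scans.

The two-stage GWAS: a genotype-free Cox null model (sex + first five PCs)
yields Martingale residuals, which are then regressed per variant on
minor-allele dosage by OLS with an intercept. QC removes variants with
missing rate > 0.05, MAF < 1%, or Hardy-Weinberg exact p < 1e-6 (hard calls
only). Genome-wide significance is flagged at p < 5e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import GenotypeMatrix
from .survival import cohort_null_residuals

logger = logging.getLogger(__name__)

GWS_THRESHOLD = 5.0e-8


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_hwe: int
    n_kept: int


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    # P(het | allele counts) by hypergeometric-style enumeration (log scale)
    logp = (
        gammaln(n + 1)
        - gammaln(homs_minor + 1)
        - gammaln(hets + 1)
        - gammaln(homs_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    G: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants with missing rate > ``max_missing``, MAF < ``min_maf``,
    or HWE exact p < ``hwe_alpha`` (HWE skipped, with a warning, for dosage data)."""
    miss = G.missing_rate
    maf = G.maf
    fail_missing = miss > max_missing
    fail_maf = maf < min_maf
    fail_hwe = np.zeros(G.n_variants, dtype=bool)
    if G.hard_calls:
        for j in np.flatnonzero(~(fail_missing | fail_maf)):
            g = G.dosage[:, j]
            g = g[~np.isnan(g)]
            counts = [int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())]
            if sum(counts) and hwe_exact_test(*counts) < hwe_alpha:
                fail_hwe[j] = True
    else:
        logger.warning("dosage genotypes: HWE exact test skipped")
    keep = ~(fail_missing | fail_maf | fail_hwe)
    report = QCReport(
        n_input=G.n_variants,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_kept=int(keep.sum()),
    )
    logger.info(
        "QC: %d variants in; removed %d (missingness), %d (MAF), %d (HWE); %d kept",
        report.n_input, report.n_removed_missing, report.n_removed_maf,
        report.n_removed_hwe, report.n_kept,
    )
    if report.n_kept == 0:
        logger.warning("QC removed every variant")
    return G.subset(variants=keep), report


def assoc_scan(residuals, G: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant OLS of Martingale residual on dosage with an intercept,
    complete cases per variant; two-sided t-test p-values.

    Returns a DataFrame with variant_id, beta, se, p, maf, n. Variants with
    constant dosage are emitted with NaN beta/se/p.
    """
    y = np.asarray(residuals, dtype=float)
    if y.size != G.n_subjects:
        raise ValueError("residuals and genotypes must align on subjects")
    X = G.dosage
    obs = ~np.isnan(X)
    n = obs.sum(axis=0).astype(float)
    Xz = np.where(obs, X, 0.0)
    sum_x = Xz.sum(axis=0)
    sum_y = obs.T @ y
    sum_xy = Xz.T @ y
    sum_xx = (Xz * Xz).sum(axis=0)
    sum_yy = obs.T @ (y * y)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = sum_xx - sum_x**2 / n
        sxy = sum_xy - sum_x * sum_y / n
        syy = sum_yy - sum_y**2 / n
        beta = sxy / sxx
        rss = syy - beta * sxy
        dof = n - 2
        sigma2 = np.where(dof > 0, rss / np.maximum(dof, 1), np.nan)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
        p = 2 * stats.t.sf(np.abs(tstat), np.maximum(dof, 1))
    const = sxx <= 0
    beta[const] = np.nan
    se[const] = np.nan
    p[const] = np.nan
    if const.any():
        logger.warning("%d variants constant after missingness; p set to NA", int(const.sum()))
    return pd.DataFrame(
        {
            "variant_id": G.variant_ids,
            "beta": beta,
            "se": se,
            "p": p,
            "maf": G.maf,
            "n": n.astype(int),
        }
    )


def stratified_scan(
    cohort: pd.DataFrame,
    G: GenotypeMatrix,
    stratum: str = "all",
    *,
    qc: bool = False,
) -> pd.DataFrame:
    """Association scan within a sex stratum.

    Refits the Cox null model inside the stratum — dropping sex as a covariate
    for single-sex strata — recomputes Martingale residuals, then scans.
    """
    if stratum == "all":
        mask = np.ones(len(cohort), dtype=bool)
        covs = ["sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
    elif stratum in ("male", "female"):
        code = 1 if stratum == "male" else 0
        mask = cohort["sex"].to_numpy() == code
        covs = ["pc1", "pc2", "pc3", "pc4", "pc5"]
    else:
        raise ValueError(f"unknown stratum: {stratum!r}")
    if not mask.any():
        raise ValueError(f"stratum {stratum!r} is empty")
    sub = cohort.loc[mask].reset_index(drop=True)
    if sub["event"].sum() == 0:
        raise ValueError(f"stratum {stratum!r} has zero events")
    Gs = G.subset(subjects=mask)
    if qc:
        Gs, _ = qc_filter(Gs)
    _, resid = cohort_null_residuals(sub, covs)
    return assoc_scan(resid, Gs)


def genomic_inflation(pvalues) -> float:
    """Genomic-control lambda: median chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def manhattan_table(results: pd.DataFrame, variant_info: pd.DataFrame | None = None) -> pd.DataFrame:
    """(chrom, pos, p) table for Manhattan plotting; parses chrom:pos:ref:alt
    ids when no variant_info is supplied."""
    if variant_info is not None:
        out = variant_info[["chrom", "pos"]].copy()
    else:
        parts = results["variant_id"].str.split(":", expand=True)
        out = pd.DataFrame({"chrom": parts[0], "pos": pd.to_numeric(parts[1], errors="coerce")})
    out["p"] = results["p"].to_numpy()
    return out
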