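"""Validation harness: self-contained experiments that exercise the pipeline
end-to-end under the synthetic study conditions.

Each function simulates its own inputs from a seed, runs the package's
estimators and tests, and returns measured quantities (calibration rates,
parameter-recovery errors, oracle agreement). The acceptance script and the
acceptance test suite both drive these; nothing here reads external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .coloc import colocalize
from .gene_based import (
    beta_maf_weights,
    burden_test,
    gene_wide_threshold,
    skat_test,
    skato_test,
)
from .gwas import assoc_scan, genomic_inflation
from .io_formats import GenotypeMatrix
from .phewas import phewas_threshold, run_phewas
from .simulate import SimConfig, simulate_coloc_region
from .survival import (
    cox_carrier_hr,
    cox_score_test,
    fit_cox,
    logrank_test,
    martingale_residuals,
)
from .variant_classes import VariantClass, build_gene_sets, classify


def _geno(dosage: np.ndarray) -> GenotypeMatrix:
    n, m = dosage.shape
    return GenotypeMatrix(
        dosage, np.array([f"S{i}" for i in range(n)]), np.array([f"v{j}" for j in range(m)])
    )


# ---------------------------------------------------------------------------
# printed Bonferroni thresholds


def bonferroni_thresholds() -> dict:
    """The two self-contained multiple-testing computations: the per-variant
    Cox screen over 587 variants and the phenome-wide screen over 1,670
    phenotypes, on the scale they are conventionally printed."""
    per_variant = gene_wide_threshold(587)  # 0.05 / 587
    full, display = phewas_threshold(1_670)
    return {
        "per_variant_threshold": float(f"{per_variant:.1e}"),  # 2 significant figures
        "per_variant_threshold_full": per_variant,
        "phewas_threshold_display": display,
        "phewas_threshold_full": full,
    }


# ---------------------------------------------------------------------------
# Martingale-residual identities


def residual_identities(seed: int = 0) -> dict:
    """Hand example (2/3, 1/6, -5/6) plus the Breslow sum-zero identity and
    the M_i <= 1 bound on a randomly fitted model."""
    fit = fit_cox([1.0, 2.0, 3.0], [1, 1, 0], None, ties="breslow")
    r = martingale_residuals(fit, [1.0, 2.0, 3.0], [1, 1, 0], None)
    hand_err = float(np.abs(r - np.array([2 / 3, 1 / 6, -5 / 6])).max())

    rng = np.random.default_rng(seed)
    n = 500
    Z = rng.standard_normal((n, 2))
    t = rng.exponential(np.exp(-(Z @ [0.4, -0.2])))
    d = (rng.random(n) < 0.7).astype(int)
    f = fit_cox(t, d, Z, ties="breslow")
    res = martingale_residuals(f, t, d, Z)
    return {
        "hand_example_max_abs_err": hand_err,
        "residual_sum_abs": float(abs(res.sum())),
        "residual_max": float(res.max()),
    }


# ---------------------------------------------------------------------------
# Cox oracle agreement


def _brute_force_loglik(beta, times, events, x):
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_oracle(seed: int = 0) -> dict:
    """One-covariate Newton fit versus direct 1-D maximization of the explicit
    partial likelihood, and score test versus log-rank on two-group data."""
    times = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
    events = np.array([1, 0, 1, 1, 0, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    fit = fit_cox(times, events, x, ties="breslow")
    res = minimize_scalar(
        lambda b: -_brute_force_loglik(b, times, events, x),
        bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
    )
    beta_diff = float(abs(fit.beta_hat[0] - res.x))

    rng = np.random.default_rng(seed)
    n = 120
    g = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(np.exp(-0.5 * g))
    d = (rng.random(n) < 0.8).astype(int)
    chi2_score, _ = cox_score_test(t, d, g, ties="breslow")
    chi2_lr, _ = logrank_test(t, d, g)
    return {
        "beta_vs_bruteforce_abs_diff": beta_diff,
        "score_vs_logrank_abs_diff": float(abs(chi2_score - chi2_lr)),
    }


# ---------------------------------------------------------------------------
# two-stage (residual scan) vs one-stage (full Cox) agreement


def two_stage_concordance(seed: int = 0, n: int = 10_000, n_snps: int = 200) -> dict:
    """Pearson correlation of -log10 p between the Martingale-residual scan
    and per-SNP full Cox Wald tests over independently simulated causal SNPs
    (MAF 0.3, per-allele log-HR 0.3)."""
    rng = np.random.default_rng(seed)
    lp_two, lp_one = [], []
    for _ in range(n_snps):
        g = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.binomial(1, 0.5, n).astype(float)
        eta = 0.3 * g + 0.3 * sex
        t = 100.0 * (rng.exponential(size=n) / np.exp(eta)) ** (1 / 7)
        c = rng.uniform(52.6, 88.7, n)
        d = (t <= c).astype(int)
        age = np.minimum(t, c)
        null = fit_cox(age, d, sex[:, None])
        resid = martingale_residuals(null, age, d, sex[:, None])
        scan = assoc_scan(resid, _geno(g[:, None]))
        lp_two.append(-np.log10(scan["p"][0]))
        full = fit_cox(age, d, np.column_stack([g, sex]))
        z = full.beta_hat[0] / full.se_beta()[0]
        lp_one.append(-np.log10(max(2 * stats.norm.sf(abs(z)), 1e-300)))
    r = float(np.corrcoef(lp_two, lp_one)[0, 1])
    return {"pearson_r": r, "n_snps": n_snps, "n": n}


# ---------------------------------------------------------------------------
# null calibration


def _rates(pvals: np.ndarray) -> dict:
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    return {
        "rate_05": float((pvals < 0.05).mean()),
        "rate_01": float((pvals < 0.01).mean()),
        "n_reps": int(pvals.size),
    }


def calibrate_burden(seed: int, reps: int = 2_000, n: int = 5_000, carrier_freq: float = 0.01) -> dict:
    rng = np.random.default_rng(seed)
    ps = []
    while len(ps) < reps:
        c = rng.binomial(1, carrier_freq, n)
        if not 0 < c.sum() < n:
            continue
        ps.append(burden_test(rng.standard_normal(n), c)[2])
    return _rates(np.array(ps))


def calibrate_skat(seed: int, reps: int = 2_000, n: int = 1_000, k: int = 8,
                   carrier_freq: float = 0.01, omnibus: bool = False) -> dict:
    rng = np.random.default_rng(seed)
    G = rng.binomial(1, carrier_freq, (n, k)).astype(float)
    test = (lambda y: skato_test(y, G).p) if omnibus else (lambda y: skat_test(y, G).p)
    ps = np.array([test(rng.standard_normal(n)) for _ in range(reps)])
    return _rates(ps)


def calibrate_assoc_scan(seed: int, n_variants: int = 20_000, n: int = 1_000,
                         n_blocks: int = 200) -> dict:
    """Null scans in independent blocks, each with its own phenotype draw,
    so the genomic-inflation estimate is not hostage to a single phenotype
    realization."""
    rng = np.random.default_rng(seed)
    per_block = n_variants // n_blocks
    ps = []
    for _ in range(n_blocks):
        G = _geno(rng.binomial(2, rng.uniform(0.05, 0.5, per_block), (n, per_block)).astype(float))
        y = rng.standard_normal(n)
        ps.append(assoc_scan(y, G)["p"].to_numpy())
    ps = np.concatenate(ps)
    out = _rates(ps)
    out["lambda_gc"] = genomic_inflation(ps)
    return out


def calibrate_logrank(seed: int, reps: int = 2_000, n: int = 100) -> dict:
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(reps):
        g = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
        t = rng.exponential(1.0, n)
        d = (rng.random(n) < 0.8).astype(int)
        ps.append(logrank_test(t, d, g)[1])
    return _rates(np.array(ps))


def calibrate_phewas_logistic(seed: int, reps: int = 2_000, n: int = 2_000) -> dict:
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 80, n)
    sex = rng.binomial(1, 0.5, n).astype(float)
    cov = pd.DataFrame({"age": age, "sex": sex})
    meta = pd.DataFrame([{"phenotype_id": "y", "kind": "binary", "code": ""}])
    logit = -1.6 + 0.01 * (age - 60) + 0.1 * sex
    prob = 1 / (1 + np.exp(-logit))
    ps = []
    for _ in range(reps):
        carrier = rng.binomial(1, 0.1, n)
        y = rng.binomial(1, prob).astype(float)
        res = run_phewas(carrier, pd.DataFrame({"y": y}), meta, covariates=cov)
        ps.append(res[0].p)
    return _rates(np.array(ps))


# ---------------------------------------------------------------------------
# SKAT / SKAT-O permutation oracle


def skat_permutation_oracle(seed: int = 11, n_perm: int = 1_000_000) -> dict:
    """n = 50, k = 3 instance near p ~ 0.01: Davies-inverted p-values against
    a large permutation null, plus the rho-grid endpoint identities."""
    rng = np.random.default_rng(seed)
    n, k = 50, 3
    G = rng.binomial(2, 0.3, (n, k)).astype(float)
    y = rng.standard_normal(n) + G @ np.array([0.35, 0.25, 0.3])
    sk = skat_test(y, G)
    so = skato_test(y, G)

    w = beta_maf_weights(G.mean(axis=0) / 2.0)
    e = y - y.mean()
    s2 = e @ e / (n - 1)
    Gw = G * w
    rng_p = np.random.default_rng(seed + 1)
    Qs = np.empty(n_perm)
    Qb = np.empty(n_perm)
    block = 100_000
    for s in range(0, n_perm, block):
        m = min(block, n_perm - s)
        Y = rng_p.permuted(np.tile(y, (m, 1)), axis=1)
        E = Y - Y.mean(axis=1, keepdims=True)
        S = E @ Gw
        Qs[s : s + m] = (S**2).sum(axis=1) / s2
        Qb[s : s + m] = S.sum(axis=1) ** 2 / s2
    p_perm = float((Qs >= sk.Q * (1 - 1e-12)).mean())
    se = float(np.sqrt(p_perm * (1 - p_perm) / n_perm))

    # rank-based permutation omnibus over the same rho grid
    rhos = np.array(so.rho_grid)
    Qr = (1 - rhos)[None, :] * Qs[:, None] + rhos[None, :] * Qb[:, None]
    S_obs = e @ Gw
    Q_obs = (1 - rhos) * sk.Q + rhos * (float(S_obs.sum()) ** 2 / s2)
    minp = np.ones(n_perm)
    for c in range(rhos.size):
        order = np.argsort(Qr[:, c])
        ranks = np.empty(n_perm)
        ranks[order] = np.arange(n_perm)
        minp = np.minimum(minp, (n_perm - ranks) / n_perm)
    obs_p = np.array([(Qr[:, c] >= Q_obs[c] * (1 - 1e-12)).mean() for c in range(rhos.size)])
    p_omni_perm = float((minp <= obs_p.min() + 1e-15).mean())
    se_omni = float(np.sqrt(p_omni_perm * (1 - p_omni_perm) / n_perm))

    endpoint_burden = skato_test(y, G, rho_grid=(1.0,))
    endpoint_skat = skato_test(y, G, rho_grid=(0.0,))
    return {
        "skat_p": sk.p,
        "skat_p_perm": p_perm,
        "skat_abs_diff": abs(sk.p - p_perm),
        "skat_3se": 3 * se,
        "skato_p": so.p,
        "skato_p_perm": p_omni_perm,
        "skato_abs_diff": abs(so.p - p_omni_perm),
        "skato_3se": 3 * se_omni,
        "rho1_equals_burden_score": endpoint_burden.p == endpoint_burden.p_rho[1.0],
        "rho0_minus_skat_abs": abs(endpoint_skat.p - sk.p),
        "min_prho": min(so.p_rho.values()),
    }


# ---------------------------------------------------------------------------
# parameter recovery


def carrier_hr_recovery(seed: int = 0, reps: int = 200, n: int = 5_000,
                        carrier_freq: float = 0.1, log_hr: float = float(np.log(2))) -> dict:
    """Mean estimated carrier log-HR over Weibull proportional-hazards
    cohorts with ~500 carriers of a ln(2) effect."""
    rng = np.random.default_rng(seed)
    betas = []
    covered = 0
    for _ in range(reps):
        carrier = rng.binomial(1, carrier_freq, n)
        sex = rng.binomial(1, 0.5, n)
        pcs = rng.standard_normal((n, 5)) * 0.01
        eta = log_hr * carrier + 0.3 * sex
        t = 100.0 * (rng.exponential(size=n) / np.exp(eta)) ** (1 / 7)
        c = rng.uniform(52.6, 88.7, n)
        cohort = pd.DataFrame(
            {"subject_id": [str(i) for i in range(n)], "event": (t <= c).astype(int),
             "age": np.minimum(t, c), "sex": sex,
             **{f"pc{j+1}": pcs[:, j] for j in range(5)}}
        )
        res = cox_carrier_hr(cohort, carrier)
        betas.append(res["beta"])
        covered += res["ci"][0] <= np.exp(log_hr) <= res["ci"][1]
    return {
        "mean_beta": float(np.mean(betas)),
        "abs_bias": float(abs(np.mean(betas) - log_hr)),
        "ci_coverage": covered / reps,
        "true_log_hr": log_hr,
    }


def coloc_recovery(seed: int = 0, reps: int = 200) -> dict:
    """Median PP4 under a shared causal variant and median PP3 under distinct
    causal variants in linkage equilibrium."""
    pp4, pp3 = [], []
    for i in range(reps):
        cfg = SimConfig(seed=seed * reps + i)
        cfg.coloc.hypothesis = "H4"
        a, b, _ = simulate_coloc_region(cfg)
        pp4.append(colocalize(a, b).pp4)
        cfg2 = SimConfig(seed=seed * reps + i + 10_000_000)
        cfg2.coloc.hypothesis = "H3"
        cfg2.coloc.ld_decay = 0.0
        a, b, _ = simulate_coloc_region(cfg2)
        pp3.append(colocalize(a, b).pp[3])
    return {"median_pp4_h4": float(np.median(pp4)), "median_pp3_h3": float(np.median(pp3))}


# ---------------------------------------------------------------------------
# VAF / CHIP operating characteristics


def vaf_operating_characteristics(seed: int = 0, reps: int = 500, n_carriers: int = 200,
                                  depth: float = 30.0, clone_fraction: float = 0.5,
                                  n_boot: int = 10_000) -> dict:
    """Flag rates and bootstrap-CI coverage: germline carriers (true mean VAF
    0.5) should rarely flag; a clone at fraction 0.5 (true mean VAF 0.25)
    should almost always flag."""
    from .vaf import compute_vaf, gene_vaf_summary

    rng = np.random.default_rng(seed)
    germ_flags = somatic_flags = cover = 0
    for _ in range(reps):
        dp = np.maximum(rng.poisson(depth, n_carriers), 1)
        vaf_g = compute_vaf(rng.binomial(dp, 0.5), dp)
        s = gene_vaf_summary(vaf_g, n_boot=n_boot, seed=rng)
        germ_flags += s.chip_flag
        cover += s.ci95[0] <= 0.5 <= s.ci95[1]
        dp = np.maximum(rng.poisson(depth, n_carriers), 1)
        vaf_s = compute_vaf(rng.binomial(dp, clone_fraction / 2.0), dp)
        somatic_flags += gene_vaf_summary(vaf_s, n_boot=n_boot, seed=rng).chip_flag
    return {
        "germline_flag_rate": germ_flags / reps,
        "somatic_flag_rate": somatic_flags / reps,
        "ci_coverage": cover / reps,
    }


# ---------------------------------------------------------------------------
# classification / filtering fixtures


def filter_fixture_checks() -> dict:
    """Exact expected memberships on constructed tables exercising the
    0.7 / 0.75 score cutoffs, the nine LoF terms, the MAF < 1% filter, the
    >= 10-carrier gate and the MAC >= 3 screen."""
    checks = []
    checks.append(classify("stop_gained") == {VariantClass.LOF})
    checks.append(classify("missense_variant", alphamissense=0.70) == {VariantClass.AM})
    checks.append(classify("missense_variant", alphamissense=0.6999) == set())
    checks.append(classify("missense_variant", revel=0.75) == {VariantClass.REVEL})
    checks.append(classify("missense_variant", alphamissense=0.5, revel=0.80) == {VariantClass.REVEL})
    for term in ("splice_acceptor_variant", "splice_donor_variant", "frameshift_variant",
                 "start_lost", "stop_lost", "transcript_ablation", "feature_elongation",
                 "feature_truncation"):
        checks.append(classify(term) == {VariantClass.LOF})
    checks.append(classify("synonymous_variant", alphamissense=0.99) == set())

    n = 4000
    dosage = np.zeros((n, 3))
    dosage[:9, 0] = 1      # 9 carriers: gated out
    dosage[:88, 1] = 1     # MAF 0.011: fails the rare filter
    dosage[9:28, 2] = 1    # 19 carriers, MAF ~0.24%: kept
    G = _geno(dosage)
    ann = pd.DataFrame(
        [
            {"variant_id": "v0", "gene": "gA", "consequence": "stop_gained",
             "alphamissense": np.nan, "revel": np.nan},
            {"variant_id": "v1", "gene": "gB", "consequence": "stop_gained",
             "alphamissense": np.nan, "revel": np.nan},
            {"variant_id": "v2", "gene": "gB", "consequence": "stop_gained",
             "alphamissense": np.nan, "revel": np.nan},
        ]
    )
    sets = build_gene_sets(G, ann, VariantClass.LOF)
    checks.append(len(sets) == 1)
    checks.append(sets and sets[0].gene == "gB" and list(sets[0].variant_ids) == ["v2"])
    checks.append(sets and sets[0].n_carriers == 19)

    from .gene_based import per_variant_cox

    rng = np.random.default_rng(0)
    n2 = 2000
    cohort = pd.DataFrame(
        {"subject_id": [str(i) for i in range(n2)], "event": 1,
         "age": rng.exponential(1, n2) * 40 + 1, "sex": rng.integers(0, 2, n2),
         **{f"pc{j}": rng.standard_normal(n2) for j in range(1, 6)}}
    )
    Gs = np.zeros((n2, 2))
    Gs[:2, 0] = 1   # MAC 2: excluded
    Gs[:30, 1] = 1  # MAC 30: tested
    table, thr = per_variant_cox(cohort, Gs, ["low", "ok"])
    checks.append(set(table["variant_id"]) == {"ok"})
    checks.append(abs(thr - 0.05) < 1e-12)
    return {"fraction_passed": float(np.mean([bool(c) for c in checks])), "n_checks": len(checks)}
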