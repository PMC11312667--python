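"""Synthetic cohorts with the statistical structure the pipeline assumes.

Survival ages are drawn by inverse transform from a Weibull baseline hazard
under proportional hazards, H(t | z) = (t/scale)^shape * exp(eta), with
administrative censoring on the age scale (each subject has a drawn "current
age"; subjects whose death age exceeds it are censored there). Common
variants are HWE genotypes; rare gene architectures are sparse Bernoulli
carriers with class labels and pathogenicity scores straddling the 0.7/0.75
cutoffs; read counts are binomial around 0.5 (germline) or clone_fraction/2
(clonal somatic); colocalization regions are multivariate-normal GWAS draws
over AR(1) LD.

A single root seed is expanded into fixed per-stage child seeds, so each
generator is reproducible on its own and consistent inside a full run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

_STAGE_KEYS = {
    "covariates": 0,
    "common_genotypes": 1,
    "gene_genotypes": 2,
    "survival": 3,
    "censoring": 4,
    "read_counts": 5,
    "coloc": 6,
    "phenotypes": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage of the simulation."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],)))


@dataclass
class VariantSpec:
    """A common variant: HWE genotype at ``maf`` with per-allele log-HR."""

    maf: float
    log_hr: float = 0.0

    def __post_init__(self):
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")


@dataclass
class GeneSpec:
    """A rare-variant gene architecture.

    ``n_variants`` qualifying variants of ``variant_class``, each carried
    (heterozygous) with probability ``carrier_freq``; carrier status of any
    qualifying variant multiplies the hazard by exp(log_hr). Damaging scores
    are drawn at or above the class cutoff (or fixed at ``score``);
    ``n_nonqualifying`` extra missense variants get sub-cutoff scores so the
    classification filters are exercised.
    """

    gene: str
    n_variants: int
    carrier_freq: float
    variant_class: str = "LoF"
    log_hr: float = 0.0
    score: float | None = None
    n_nonqualifying: int = 0

    def __post_init__(self):
        if not 0 < self.carrier_freq < 1:
            raise ValueError("carrier_freq must be in (0, 1)")
        if self.variant_class not in ("LoF", "AlphaMissense", "REVEL"):
            raise ValueError(f"unknown variant class: {self.variant_class!r}")


@dataclass
class SomaticSpec:
    clone_fraction: float = 0.5
    mean_depth: float = 30.0

    def __post_init__(self):
        if not 0 < self.clone_fraction < 1:
            raise ValueError("clone_fraction must be in (0, 1)")


@dataclass
class ColocSpec:
    n_variants: int = 100
    ld_decay: float = 0.9  # AR(1) correlation parameter between adjacent variants
    n_a: int = 10_000
    n_b: int = 1_000
    hypothesis: str = "H4"  # generative truth in {H0..H4}
    z_causal: float = 10.0

    def __post_init__(self):
        if self.hypothesis not in {"H0", "H1", "H2", "H3", "H4"}:
            raise ValueError(f"unknown hypothesis: {self.hypothesis!r}")


@dataclass
class PhenotypeSpec:
    phenotype_id: str
    kind: str = "binary"  # or "continuous"
    code: str = ""
    prevalence: float = 0.1  # binary baseline prevalence
    carrier_effect: float = 0.0  # log-OR (binary) or mean shift (continuous)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the scale-free features of the source cohort: an elderly
    biobank with ~10% observed mortality, administrative censoring at last
    known ages spanning roughly 53-89 years, modest male excess mortality,
    and null principal components.
    """

    n_subjects: int = 10_000
    seed: int = 0
    weibull_shape: float = 7.0
    weibull_scale: float = 100.0
    censoring: tuple = ("uniform", 52.6, 88.7)
    sex_log_hr: float = 0.35
    pc_log_hrs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    variants: list[VariantSpec] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    somatic: SomaticSpec = field(default_factory=SomaticSpec)
    coloc: ColocSpec = field(default_factory=ColocSpec)
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


def weibull_median(config: SimConfig) -> float:
    """Closed-form baseline median survival age: scale * (ln 2)^(1/shape)."""
    return config.weibull_scale * np.log(2.0) ** (1.0 / config.weibull_shape)


def _censor_ages(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind, *args = config.censoring
    n = config.n_subjects
    if kind == "none":
        return np.full(n, np.inf)
    if kind == "uniform":
        lo, hi = args
        ages = rng.uniform(lo, hi, size=n)
    elif kind == "fixed":
        ages = np.full(n, float(args[0]))
    elif kind == "event_fraction":
        # single administrative censor age at the baseline Weibull quantile
        # leaving `frac` of baseline subjects alive (hence censored)
        frac = float(args[0])
        if not 0 < frac < 1:
            raise ValueError("censored fraction must be in (0, 1)")
        ages = np.full(n, config.weibull_scale * (-np.log(frac)) ** (1.0 / config.weibull_shape))
    else:
        raise ValueError(f"unknown censoring spec: {kind!r}")
    if np.all(ages <= 0):
        raise ValueError("degenerate censoring: every subject censored at age <= 0")
    return ages


def _gene_variant_ids(config: SimConfig) -> dict[str, tuple[list[str], list[str]]]:
    """Stable synthetic chrom:pos:ref:alt ids per gene: (qualifying, nonqualifying)."""
    out = {}
    pos = 1_000_000
    for gi, gs in enumerate(config.genes):
        chrom = str(2 + gi)
        qual = [f"{chrom}:{pos + j}:C:T" for j in range(gs.n_variants)]
        nonq = [f"{chrom}:{pos + gs.n_variants + j}:G:A" for j in range(gs.n_nonqualifying)]
        pos += 10_000
        out[gs.gene] = (qual, nonq)
    return out


def _simulate_gene_genotypes(config: SimConfig) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Bernoulli heterozygous carriers for every gene spec, plus annotations."""
    rng = stage_rng(config.seed, "gene_genotypes")
    ids_map = _gene_variant_ids(config)
    n = config.n_subjects
    cols, ids, ann_rows = [], [], []
    lof_terms = ["stop_gained", "frameshift_variant", "splice_acceptor_variant",
                 "splice_donor_variant", "start_lost", "stop_lost",
                 "transcript_ablation", "feature_elongation", "feature_truncation"]
    for gs in config.genes:
        qual, nonq = ids_map[gs.gene]
        for j, vid in enumerate(qual):
            cols.append(rng.binomial(1, gs.carrier_freq, size=n).astype(float))
            ids.append(vid)
            if gs.variant_class == "LoF":
                ann_rows.append({"variant_id": vid, "gene": gs.gene,
                                 "consequence": lof_terms[j % len(lof_terms)],
                                 "alphamissense": np.nan, "revel": np.nan})
            else:
                cutoff = 0.7 if gs.variant_class == "AlphaMissense" else 0.75
                score = gs.score if gs.score is not None else float(rng.uniform(cutoff, 1.0))
                ann_rows.append({"variant_id": vid, "gene": gs.gene,
                                 "consequence": "missense_variant",
                                 "alphamissense": score if gs.variant_class == "AlphaMissense" else np.nan,
                                 "revel": score if gs.variant_class == "REVEL" else np.nan})
        for vid in nonq:
            cols.append(rng.binomial(1, gs.carrier_freq, size=n).astype(float))
            ids.append(vid)
            ann_rows.append({"variant_id": vid, "gene": gs.gene,
                             "consequence": "missense_variant",
                             "alphamissense": float(rng.uniform(0.2, 0.699)),
                             "revel": float(rng.uniform(0.2, 0.749))})
    dosage = np.column_stack(cols) if cols else np.empty((n, 0))
    ann = pd.DataFrame(ann_rows, columns=["variant_id", "gene", "consequence", "alphamissense", "revel"])
    return dosage, ids, ann


def simulate_gene_burden(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Rare-variant genotypes plus an annotation table for every gene spec."""
    dosage, ids, ann = _simulate_gene_genotypes(config)
    subjects = np.array([f"S{i:07d}" for i in range(config.n_subjects)])
    G = GenotypeMatrix(dosage=dosage, subject_ids=subjects, variant_ids=np.array(ids, dtype=object))
    return G, ann


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GenotypeMatrix, dict]:
    """Cohort table, genotype matrix (common + rare gene variants) and the
    generative truth record.

    Death ages follow the Weibull proportional-hazards model
    t = scale * (E / exp(eta))^(1/shape), E ~ Exp(1), with
    eta = sex*b_sex + PC*b_pc + sum_j g_j*gamma_j + sum_genes carrier*gamma_g.
    """
    n = config.n_subjects
    rng_cov = stage_rng(config.seed, "covariates")
    sex = rng_cov.binomial(1, 0.5, size=n).astype(float)
    pcs = rng_cov.standard_normal((n, 5))

    rng_g = stage_rng(config.seed, "common_genotypes")
    common_cols, common_ids = [], []
    for j, vs in enumerate(config.variants):
        common_cols.append(rng_g.binomial(2, vs.maf, size=n).astype(float))
        common_ids.append(f"1:{10_000 + j}:A:G")
    gene_dosage, gene_ids, _ = _simulate_gene_genotypes(config)

    eta = sex * config.sex_log_hr + pcs @ np.asarray(config.pc_log_hrs, dtype=float)
    for col, vs in zip(common_cols, config.variants):
        eta = eta + col * vs.log_hr
    carrier_truth = {}
    col0 = 0
    for gs in config.genes:
        qual = gene_dosage[:, col0 : col0 + gs.n_variants]
        carrier = (qual > 0).any(axis=1).astype(float)
        carrier_truth[gs.gene] = carrier
        eta = eta + carrier * gs.log_hr
        col0 += gs.n_variants + gs.n_nonqualifying

    rng_t = stage_rng(config.seed, "survival")
    E = rng_t.exponential(size=n)
    death_age = config.weibull_scale * (E / np.exp(eta)) ** (1.0 / config.weibull_shape)

    rng_c = stage_rng(config.seed, "censoring")
    censor_age = _censor_ages(config, rng_c)
    event = (death_age <= censor_age).astype(int)
    age = np.where(event == 1, death_age, censor_age)
    age = np.maximum(age, 1e-6)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:07d}" for i in range(n)],
            "event": event,
            "age": age,
            "sex": sex.astype(int),
            **{f"pc{k+1}": pcs[:, k] for k in range(5)},
        }
    )
    dosage = np.column_stack(common_cols + [gene_dosage]) if (common_cols or gene_ids) else np.empty((n, 0))
    if not common_cols and not gene_ids:
        dosage = np.empty((n, 0))
    G = GenotypeMatrix(
        dosage=dosage,
        subject_ids=cohort["subject_id"].to_numpy(),
        variant_ids=np.array(common_ids + gene_ids, dtype=object),
    )
    truth = {
        "config": config,
        "death_age": death_age,
        "censor_age": censor_age,
        "eta": eta,
        "variant_log_hrs": {vid: vs.log_hr for vid, vs in zip(common_ids, config.variants)},
        "gene_log_hrs": {gs.gene: gs.log_hr for gs in config.genes},
        "gene_carriers": carrier_truth,
    }
    return cohort, G, truth


def simulate_read_counts(carriers, somatic: bool, config: SimConfig) -> pd.DataFrame:
    """Per-carrier read counts: depth ~ Poisson(mean_depth) truncated at >= 1;
    alt ~ Binomial(depth, 0.5) for germline, Binomial(depth, f/2) for a clonal
    somatic variant at clone fraction f.

    ``carriers`` is either an integer count or a DataFrame with subject_id and
    variant_id columns.
    """
    if config.somatic.mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    rng = stage_rng(config.seed, "read_counts")
    if isinstance(carriers, int):
        frame = pd.DataFrame(
            {"subject_id": [f"S{i:07d}" for i in range(carriers)],
             "variant_id": ["sim:1:A:G"] * carriers}
        )
    else:
        frame = carriers[["subject_id", "variant_id"]].copy()
    n = len(frame)
    depth = rng.poisson(config.somatic.mean_depth, size=n)
    while (depth == 0).any():  # truncate at >= 1
        zero = depth == 0
        depth[zero] = rng.poisson(config.somatic.mean_depth, size=int(zero.sum()))
    p_alt = config.somatic.clone_fraction / 2.0 if somatic else 0.5
    alt = rng.binomial(depth, p_alt)
    frame["alt_reads"] = alt
    frame["depth"] = depth
    return frame


def ar1_corr(m: int, r: float) -> np.ndarray:
    idx = np.arange(m)
    return r ** np.abs(idx[:, None] - idx[None, :])


def simulate_coloc_region(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired summary statistics for two traits over an AR(1)-LD region.

    Marginal z-scores are drawn MVN(Sigma @ lam, Sigma), where lam carries the
    causal z at the causal position(s); betas are z * se with se = 1/sqrt(n).
    The generative truth (H0..H4 and causal indices) is returned alongside.
    """
    spec = config.coloc
    m = spec.n_variants
    Sigma = ar1_corr(m, spec.ld_decay)
    try:
        L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise ValueError("LD matrix is not positive definite") from exc
    rng = stage_rng(config.seed, "coloc")
    causal_a = m // 2
    causal_b = causal_a if spec.hypothesis == "H4" else (m // 4 if m >= 4 else 0)
    lam_a = np.zeros(m)
    lam_b = np.zeros(m)
    if spec.hypothesis in ("H1", "H3", "H4"):
        lam_a[causal_a] = spec.z_causal
    if spec.hypothesis in ("H2", "H4"):
        lam_b[causal_b if spec.hypothesis == "H2" else causal_a] = spec.z_causal
    if spec.hypothesis == "H3":
        lam_b[causal_b] = spec.z_causal
    z_a = Sigma @ lam_a + L @ rng.standard_normal(m)
    z_b = Sigma @ lam_b + L @ rng.standard_normal(m)
    se_a = np.full(m, 1.0 / np.sqrt(spec.n_a))
    se_b = np.full(m, 1.0 / np.sqrt(spec.n_b))
    ids = [f"9:{100_000 + 1_000 * j}:A:G" for j in range(m)]
    df_a = pd.DataFrame({"variant_id": ids, "beta": z_a * se_a, "se": se_a,
                         "p": 1.0, "maf": 0.3, "n": spec.n_a})
    df_b = pd.DataFrame({"variant_id": ids, "beta": z_b * se_b, "se": se_b,
                         "p": 1.0, "maf": 0.3, "n": spec.n_b})
    truth = {"hypothesis": spec.hypothesis, "causal_a": causal_a if lam_a.any() else None,
             "causal_b": (causal_b if spec.hypothesis in ("H2", "H3") else causal_a) if lam_b.any() else None}
    return df_a, df_b, truth


def simulate_phenotypes(config: SimConfig, carrier, covariates: pd.DataFrame | None = None):
    """Phenotype matrix + metadata for the PheWAS stage.

    Binary phenotypes are Bernoulli with logit(prevalence) + carrier_effect *
    carrier; continuous phenotypes are standard normal + carrier_effect * carrier.
    """
    rng = stage_rng(config.seed, "phenotypes")
    carrier = np.asarray(carrier, dtype=float)
    n = carrier.size
    values = {}
    meta_rows = []
    for ps in config.phenotypes:
        if ps.kind == "binary":
            logit0 = np.log(ps.prevalence / (1 - ps.prevalence))
            p = 1.0 / (1.0 + np.exp(-(logit0 + ps.carrier_effect * carrier)))
            values[ps.phenotype_id] = rng.binomial(1, p).astype(float)
        else:
            values[ps.phenotype_id] = rng.standard_normal(n) + ps.carrier_effect * carrier
        meta_rows.append({"phenotype_id": ps.phenotype_id, "kind": ps.kind, "code": ps.code})
    idx = pd.Index([f"S{i:07d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(values, index=idx), pd.DataFrame(meta_rows, columns=["phenotype_id", "kind", "code"])
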