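"""On-disk formats: cohort and phenotype tables, genotypes, annotations, read counts,
summary statistics.

All tabular artifacts are TSV with a header row. Genotypes come either from a VCF
(hard calls from GT, optional per-carrier read counts from AD/DP) or from a dosage
TSV (variants as rows, subjects as columns). Dosages are always stored
minor-allele-oriented: the allele with sample frequency <= 0.5 is the counted one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "event", "age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
ANNOTATION_COLUMNS = ["variant_id", "gene", "consequence", "alphamissense", "revel"]
READCOUNT_COLUMNS = ["subject_id", "variant_id", "alt_reads", "depth"]
SUMMARY_COLUMNS = ["variant_id", "beta", "se", "p", "maf", "n"]

#: format used for real-valued columns on disk; round-trips doubles exactly
_FLOAT_FMT = "%.17g"


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix (subjects x variants).

    ``dosage`` holds minor-allele counts in [0, 2]; missing entries are ``nan``
    and are never imputed — per-variant MAF/MAC/missingness are computed over
    the non-missing entries only.
    """

    dosage: np.ndarray
    subject_ids: np.ndarray
    variant_ids: np.ndarray
    hard_calls: bool = True
    flipped: np.ndarray | None = None
    variant_info: pd.DataFrame | None = None
    read_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.variant_ids = np.asarray(self.variant_ids)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (subjects x variants)")
        if self.dosage.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise ValueError("dosage shape does not match subject/variant ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0.0) < 0 or np.nanmax(self.dosage, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.flipped is None:
            self.flipped = np.zeros(self.n_variants, dtype=bool)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    @property
    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the counted (minor-oriented) allele per variant."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.counted_allele_freq
        return np.minimum(f, 1.0 - f)

    @property
    def mac(self) -> np.ndarray:
        """Minor allele count over non-missing entries."""
        return np.nansum(self.dosage, axis=0)

    def subset(self, subjects=None, variants=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index arrays."""
        si = np.arange(self.n_subjects) if subjects is None else np.asarray(subjects)
        vi = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        info = self.variant_info.iloc[vi].reset_index(drop=True) if self.variant_info is not None else None
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(si, vi)],
            subject_ids=self.subject_ids[si],
            variant_ids=self.variant_ids[vi],
            hard_calls=self.hard_calls,
            flipped=self.flipped[vi],
            variant_info=info,
            read_counts=self.read_counts,
        )


def orient_minor_allele(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip variants whose counted-allele frequency exceeds 0.5 (ties kept as-is).

    Returns the oriented dosage and a per-variant boolean flip indicator.
    """
    dosage = np.array(dosage, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dosage, axis=0) / 2.0
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]
    return dosage, flip


# ---------------------------------------------------------------------------
# cohort table


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing required columns: {missing_cols}")
    df = df[COHORT_COLUMNS].copy()
    bad = df.index[df[COHORT_COLUMNS[1:]].isna().any(axis=1) | df["subject_id"].isna()]
    if len(bad):
        raise ValueError(f"cohort rows with missing required fields: {list(bad[:20])}")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dups[:10]}")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    df["age"] = df["age"].astype(float)
    nonpos = df.index[df["age"] <= 0]
    if len(nonpos):
        raise ValueError(f"non-positive age at rows: {list(nonpos[:20])}")
    df["sex"] = df["sex"].astype(int)
    for c in ["pc1", "pc2", "pc3", "pc4", "pc5"]:
        df[c] = df[c].astype(float)
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort TSV (subject_id, event, age, sex, pc1..pc5)."""
    return validate_cohort(pd.read_csv(path, sep="\t"))


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# variant annotations


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    for c in ("alphamissense", "revel"):
        df[c] = df[c].astype(float)
        vals = df[c].dropna()
        if len(vals) and ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{c} scores must lie in [0, 1]")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# read counts


def read_read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READCOUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read-count table missing columns: {missing}")
    df = df[READCOUNT_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["alt_reads"] = df["alt_reads"].astype(int)
    df["depth"] = df["depth"].astype(int)
    if (df["alt_reads"] < 0).any():
        raise ValueError("alt_reads must be nonnegative")
    if (df["alt_reads"] > df["depth"]).any():
        raise ValueError("alt_reads cannot exceed depth")
    return df


def write_read_counts(df: pd.DataFrame, path) -> None:
    df[READCOUNT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics


def write_summary_stats(results, path) -> None:
    """Write association results as TSV with fixed column order.

    ``results`` is a DataFrame (or records) with variant_id, beta, se, p, maf, n.
    p-values are written in full-precision scientific notation.
    """
    df = pd.DataFrame(results)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    df = df[SUMMARY_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    return df[SUMMARY_COLUMNS]


# ---------------------------------------------------------------------------
# phenotype matrix


def read_phenotypes(values_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a subjects x phenotypes value TSV plus metadata TSV (id, kind, code)."""
    values = pd.read_csv(values_path, sep="\t")
    if "subject_id" not in values.columns:
        raise ValueError("phenotype value table needs a subject_id column")
    values["subject_id"] = values["subject_id"].astype(str)
    values = values.set_index("subject_id")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"phenotype_id": str, "kind": str, "code": str})
    for c in ("phenotype_id", "kind", "code"):
        if c not in meta.columns:
            raise ValueError(f"phenotype metadata missing column: {c}")
    if meta["phenotype_id"].duplicated().any():
        raise ValueError("phenotype ids must be unique")
    unknown = set(meta["kind"]) - {"binary", "continuous"}
    if unknown:
        raise ValueError(f"unknown phenotype kinds: {sorted(unknown)}")
    return values, meta


def write_phenotypes(values: pd.DataFrame, meta: pd.DataFrame, values_path, meta_path) -> None:
    values.reset_index().rename(columns={"index": "subject_id"}).to_csv(
        values_path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (hard calls, AD/DP read counts when present)
    or a dosage TSV (variants as rows, subjects as columns)."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    subjects = np.asarray(vcf.samples)
    dosages: list[np.ndarray] = []
    ids: list[str] = []
    info_rows: list[dict] = []
    rc_rows: list[dict] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d (%d ALT alleles)", var.CHROM, var.POS, len(var.ALT))
            continue
        vid = f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        dosages.append(dos)
        ids.append(vid)
        info_rows.append({"chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]})
        ad = var.format("AD")
        dp = var.format("DP")
        if ad is not None and dp is not None:
            for si, subj in enumerate(subjects):
                depth = int(dp[si][0]) if dp[si][0] >= 0 else 0
                alt = int(ad[si][1]) if ad.shape[1] > 1 and ad[si][1] >= 0 else 0
                if depth > 0 and dos[si] > 0:
                    rc_rows.append(
                        {"subject_id": str(subj), "variant_id": vid, "alt_reads": alt, "depth": depth}
                    )
    if not dosages:
        raise ValueError(f"no usable biallelic sites in {path}")
    dosage = np.column_stack(dosages)
    dosage, flip = orient_minor_allele(dosage)
    return GenotypeMatrix(
        dosage=dosage,
        subject_ids=subjects.astype(str),
        variant_ids=np.asarray(ids),
        hard_calls=True,
        flipped=flip,
        variant_info=pd.DataFrame(info_rows),
        read_counts=pd.DataFrame(rc_rows, columns=READCOUNT_COLUMNS) if rc_rows else None,
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosage = df.to_numpy(dtype=float).T  # file is variants x subjects
    dosage, flip = orient_minor_allele(dosage)
    hard = bool(np.all(np.isin(dosage[~np.isnan(dosage)], [0.0, 1.0, 2.0])))
    return GenotypeMatrix(
        dosage=dosage,
        subject_ids=df.columns.to_numpy(dtype=str),
        variant_ids=df.index.to_numpy(dtype=str),
        hard_calls=hard,
        flipped=flip,
    )


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosage.T, index=G.variant_ids, columns=G.subject_ids)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
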