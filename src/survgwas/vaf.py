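"""Variant allele fractions and CHIP (clonal hematopoiesis) flagging.

Germline heterozygous carriers center near VAF = 0.5; somatic clonal variants
sit lower (a clone at fraction f of cells gives expected VAF f/2). A gene/class
VAF distribution is summarized by its mean with a percentile bootstrap 95% CI
(10,000 resamples); the distribution is flagged as left-shifted — putatively
somatic / CHIP — when the upper CI bound lies below 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def compute_vaf(alt_reads, depth) -> np.ndarray:
    """alt_reads / depth per record; zero-depth records are dropped (warned)."""
    alt = np.asarray(alt_reads, dtype=float)
    dp = np.asarray(depth, dtype=float)
    if np.any(alt < 0):
        raise ValueError("alt_reads must be nonnegative")
    if np.any(alt > dp):
        raise ValueError("alt_reads cannot exceed depth")
    ok = dp > 0
    if not ok.all():
        logger.warning("%d records with zero depth skipped", int((~ok).sum()))
    return alt[ok] / dp[ok]


@dataclass
class VafGeneSummary:
    gene: str
    variant_class: str
    vafs: np.ndarray
    mean_vaf: float
    ci95: tuple[float, float]
    n_boot: int
    chip_flag: bool

    @property
    def n(self) -> int:
        return self.vafs.size


def gene_vaf_summary(
    vafs,
    gene: str = "",
    variant_class: str = "",
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> VafGeneSummary:
    """Mean VAF with percentile-bootstrap 95% CI; chip_flag = (upper < 0.5).

    With fewer than two observations the CI degenerates to the point value
    (warned) and the flag follows the same rule.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size == 0:
        raise ValueError("no VAF observations")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("VAFs must lie in [0, 1]")
    mean = float(v.mean())
    if v.size < 2:
        logger.warning("fewer than 2 VAF observations for %s/%s; degenerate CI", gene, variant_class)
        lo = hi = mean
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        boot_means = v[idx].mean(axis=1)
        lo, hi = (float(q) for q in np.percentile(boot_means, [2.5, 97.5]))
    return VafGeneSummary(
        gene=gene,
        variant_class=variant_class,
        vafs=v,
        mean_vaf=mean,
        ci95=(lo, hi),
        n_boot=n_boot,
        chip_flag=bool(hi < 0.5),
    )


def summarize_read_counts(
    read_counts: pd.DataFrame,
    annotations: pd.DataFrame,
    class_flags: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    bootstrap_unit: str = "carrier",
) -> list[VafGeneSummary]:
    """Per-gene, per-class VAF summaries from a carrier read-count table.

    ``bootstrap_unit`` is ``"carrier"`` (resample carrier-level VAFs, default)
    or ``"variant"`` (mean per variant first, then resample variants).
    """
    from .variant_classes import classify_table

    ann = class_flags if class_flags is not None else classify_table(annotations)
    merged = read_counts.merge(ann, on="variant_id", how="inner")
    rng = np.random.default_rng(seed)
    out = []
    for flag, label in (("is_lof", "LoF"), ("is_am", "AlphaMissense"), ("is_revel", "REVEL")):
        for gene, sub in merged.loc[merged[flag]].groupby("gene", sort=True):
            vafs = compute_vaf(sub["alt_reads"], sub["depth"])
            if vafs.size == 0:
                continue
            if bootstrap_unit == "variant":
                df = sub.loc[sub["depth"] > 0]
                vafs = (
                    (df["alt_reads"] / df["depth"]).groupby(df["variant_id"]).mean().to_numpy()
                )
            out.append(
                gene_vaf_summary(vafs, gene=str(gene), variant_class=label, n_boot=n_boot, seed=rng)
            )
    return out


def summary_table(summaries: list[VafGeneSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "class": s.variant_class,
                "n": s.n,
                "mean_vaf": s.mean_vaf,
                "ci_lower": s.ci95[0],
                "ci_upper": s.ci95[1],
                "chip_flag": s.chip_flag,
            }
            for s in summaries
        ]
    )
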