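"""Rare-variant pathogenicity classes and per-gene variant sets.

Three non-exclusive classes: predicted loss-of-function (nine Sequence
Ontology consequence terms), AlphaMissense-damaging missense (score >= 0.7)
and REVEL-damaging missense (score >= 0.75). Gene sets keep variants with
cohort MAF < 1% and are tested only when they have at least 10 carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


class VariantClass(str, Enum):
    LOF = "LoF"
    AM = "AlphaMissense"
    REVEL = "REVEL"


AM_CUTOFF = 0.7
REVEL_CUTOFF = 0.75

#: loss-of-function consequence terms (normalized); both bare and VEP
#: serializations ("stop_gained" vs "stop gained", "start_lost" etc.) match
_LOF_TERMS = {
    "splice_acceptor", "splice_acceptor_variant",
    "splice_donor", "splice_donor_variant",
    "stop_gained",
    "frameshift", "frameshift_variant",
    "start_loss", "start_lost",
    "stop_loss", "stop_lost",
    "transcript_ablation",
    "feature_elongation",
    "feature_truncation",
}

_KNOWN_TERMS = _LOF_TERMS | {
    "missense", "missense_variant", "synonymous", "synonymous_variant",
    "intron_variant", "intergenic_variant", "5_prime_utr_variant",
    "3_prime_utr_variant", "upstream_gene_variant", "downstream_gene_variant",
    "splice_region_variant", "inframe_deletion", "inframe_insertion",
}

_warned_terms: set[str] = set()


def _normalize(term: str) -> str:
    return str(term).strip().lower().replace(" ", "_")


def _is_missense(term: str) -> bool:
    return "missense" in term


def classify(consequence: str, alphamissense: float | None = None, revel: float | None = None) -> set[VariantClass]:
    """Classes for one annotated variant. A variant can belong to several
    classes; AM/REVEL require a missense consequence and a score at or above
    the 0.7 / 0.75 cutoff (inclusive)."""
    term = _normalize(consequence)
    out: set[VariantClass] = set()
    if term in _LOF_TERMS:
        out.add(VariantClass.LOF)
    elif _is_missense(term):
        if alphamissense is not None and not np.isnan(alphamissense) and alphamissense >= AM_CUTOFF:
            out.add(VariantClass.AM)
        if revel is not None and not np.isnan(revel) and revel >= REVEL_CUTOFF:
            out.add(VariantClass.REVEL)
    elif term not in _KNOWN_TERMS:
        if term not in _warned_terms:
            _warned_terms.add(term)
            logger.warning("unknown consequence term %r: assigned no class", term)
    return out


def classify_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classify over an annotation table; adds boolean is_lof /
    is_am / is_revel columns."""
    df = annotations.copy()
    terms = df["consequence"].map(_normalize)
    for term in set(terms) - _KNOWN_TERMS:
        if not any(c in term for c in ("missense",)) and term not in _warned_terms:
            _warned_terms.add(term)
            logger.warning("unknown consequence term %r: assigned no class", term)
    missense = terms.map(_is_missense)
    df["is_lof"] = terms.isin(_LOF_TERMS).to_numpy()
    df["is_am"] = (missense & (df["alphamissense"] >= AM_CUTOFF)).fillna(False).to_numpy()
    df["is_revel"] = (missense & (df["revel"] >= REVEL_CUTOFF)).fillna(False).to_numpy()
    return df


@dataclass
class GeneVariantSet:
    gene: str
    variant_class: VariantClass
    variant_ids: np.ndarray
    variant_idx: np.ndarray  # column indices into the source GenotypeMatrix
    n_variants: int
    n_carriers: int

    def dosage(self, G: GenotypeMatrix) -> np.ndarray:
        return G.dosage[:, self.variant_idx]


def build_gene_sets(
    G: GenotypeMatrix,
    annotations: pd.DataFrame,
    variant_class: VariantClass,
    max_maf: float = 0.01,
    min_carriers: int = 10,
) -> list[GeneVariantSet]:
    """Per-gene sets of class variants with MAF < ``max_maf``; sets with fewer
    than ``min_carriers`` carriers are dropped (logged). A carrier is any
    subject with dosage > 0 at >= 1 member variant; missing dosages count as 0."""
    flag = {"LoF": "is_lof", "AlphaMissense": "is_am", "REVEL": "is_revel"}[VariantClass(variant_class).value]
    ann = classify_table(annotations)
    col_of = {v: j for j, v in enumerate(G.variant_ids)}
    unmatched = [v for v in ann["variant_id"] if v not in col_of]
    if unmatched:
        logger.warning("%d annotated variants absent from the genotype matrix", len(unmatched))
    maf = G.maf
    sets: list[GeneVariantSet] = []
    n_gate_dropped = 0
    for gene, sub in ann.loc[ann[flag]].groupby("gene", sort=True):
        idx = np.array([col_of[v] for v in sub["variant_id"] if v in col_of], dtype=int)
        idx = idx[maf[idx] < max_maf]
        if idx.size == 0:
            continue
        carriers = int((np.nan_to_num(G.dosage[:, idx]) > 0).any(axis=1).sum())
        if carriers < min_carriers:
            n_gate_dropped += 1
            continue
        sets.append(
            GeneVariantSet(
                gene=str(gene),
                variant_class=VariantClass(variant_class),
                variant_ids=G.variant_ids[idx],
                variant_idx=idx,
                n_variants=int(idx.size),
                n_carriers=carriers,
            )
        )
    if n_gate_dropped:
        logger.info(
            "%s: dropped %d gene sets with < %d carriers", VariantClass(variant_class).value,
            n_gate_dropped, min_carriers,
        )
    return sets


def class_overlap(annotations: pd.DataFrame) -> tuple[float, float]:
    """(fraction of AlphaMissense-damaging variants also REVEL-damaging,
    fraction of REVEL-damaging variants also AlphaMissense-damaging).

    NaN for an empty class.
    """
    ann = classify_table(annotations)
    n_am = int(ann["is_am"].sum())
    n_revel = int(ann["is_revel"].sum())
    n_both = int((ann["is_am"] & ann["is_revel"]).sum())
    frac_am = n_both / n_am if n_am else float("nan")
    frac_revel = n_both / n_revel if n_revel else float("nan")
    return frac_am, frac_revel
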