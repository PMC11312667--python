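"""Bayesian colocalization of two association signals from summary statistics.

Per-variant evidence is the Wakefield approximate Bayes factor
log ABF = 1/2 log(se^2 / (se^2 + W^2)) + 1/2 z^2 W^2 / (se^2 + W^2),
with prior effect standard deviation W. Hypothesis posteriors PP0-PP4
(no signal / trait A only / trait B only / distinct causal variants /
shared causal variant) come from log-sum-exp-stabilized sums of ABFs with
per-variant priors p1, p2, p12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIOR_SD = 0.15  # quantitative-trait prior on the effect size
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


def log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD) -> np.ndarray:
    """Wakefield log approximate Bayes factor (H1 vs H0) per variant."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log1p(-r) + 0.5 * z2 * r


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_variants: int
    labf_a: np.ndarray
    labf_b: np.ndarray
    variant_ids: np.ndarray

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def as_dict(self) -> dict:
        return {f"PP{i}": float(self.pp[i]) for i in range(5)}


def _flip_key(vid: str) -> str:
    parts = vid.split(":")
    if len(parts) == 4:
        return ":".join([parts[0], parts[1], parts[3], parts[2]])
    return vid


def harmonize(trait_a: pd.DataFrame, trait_b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect the two summary tables on chrom:pos:ref:alt keys, flipping
    trait B's beta sign where ref/alt are swapped."""
    b = trait_b.copy()
    keys_a = set(trait_a["variant_id"])
    swap = ~b["variant_id"].isin(keys_a) & b["variant_id"].map(_flip_key).isin(keys_a)
    b.loc[swap, "beta"] = -b.loc[swap, "beta"]
    b.loc[swap, "variant_id"] = b.loc[swap, "variant_id"].map(_flip_key)
    shared = sorted(keys_a & set(b["variant_id"]))
    if not shared:
        raise ValueError("no shared variants between the two traits")
    a = trait_a.set_index("variant_id").loc[shared].reset_index()
    b = b.set_index("variant_id").loc[shared].reset_index()
    return a, b


def colocalize(
    trait_a: pd.DataFrame,
    trait_b: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> ColocResult:
    """Posterior probabilities PP0-PP4 for two single-causal-variant signals.

    Inputs are summary tables with variant_id, beta, se; variants are
    intersected (with allele-flip harmonization) before analysis.
    """
    a, b = harmonize(trait_a, trait_b)
    l1 = log_abf(a["beta"], a["se"], prior_sd)
    l2 = log_abf(b["beta"], b["se"], prior_sd)
    lsum = l1 + l2
    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(lsum)
    lh0 = 0.0
    lh1 = np.log(p1) + lse1
    lh2 = np.log(p2) + lse2
    # H3: distinct causal pairs = all pairs minus same-variant pairs
    both = lse1 + lse2
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = both + np.log1p(-np.exp(np.minimum(lse12 - both, 0.0)))
    if not np.isfinite(diff):  # single shared variant: no distinct pair exists
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + diff
    lh4 = np.log(p12) + lse12
    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(
        pp=pp,
        n_variants=len(a),
        labf_a=np.asarray(l1),
        labf_b=np.asarray(l2),
        variant_ids=a["variant_id"].to_numpy(),
    )
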