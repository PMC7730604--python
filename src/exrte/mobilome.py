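"""Copy-number variation across cultivars via the ACM ratio.

For each element and cultivar, genomic read depth is normalised by the mean
depth of single-copy reference genes in that cultivar (cancelling library
size).  The ACM ratio divides each cultivar's normalised coverage by the
element's minimum across cultivars, so the least-copy cultivar sits at 1 and
values above a cutoff indicate additional copies.  The cutoff is derived
from the reference genes themselves (max/min ACM per gene, maximised over
genes); an element with ACM above the cutoff in more than one cultivar is
assigned to the mobile group (group1), otherwise group2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cutoff reported for the original reference-gene panel; usable as an override.
DEFAULT_ACM_CUTOFF = 1.7


class AcmUndefinedError(ValueError):
    """Raised when an ACM ratio cannot be formed (zero minimum coverage)."""


@dataclass
class AcmProfile:
    rte_id: str
    normalized_coverage: dict[str, float]
    acm: dict[str, float]
    n_above_cutoff: int
    group: str  # "group1" | "group2"


def normalize_coverage(rte_depth: float, ref_depths: list[float]) -> float:
    """Element depth divided by the unweighted mean reference-gene depth."""
    if not ref_depths:
        raise ValueError("need at least one reference gene depth")
    mean_ref = float(np.mean(ref_depths))
    if mean_ref <= 0:
        raise AcmUndefinedError("normalization impossible: reference depths are zero")
    if rte_depth < 0:
        raise ValueError("depth must be non-negative")
    return rte_depth / mean_ref


def acm_ratios(values: dict[str, float]) -> dict[str, float]:
    """Each cultivar's normalised coverage divided by the minimum across cultivars."""
    if len(values) < 2:
        raise ValueError("ACM needs at least two cultivars")
    vmin = min(values.values())
    if vmin <= 0:
        raise AcmUndefinedError(
            "element absent in some cultivar; report as presence/absence variation"
        )
    return {c: v / vmin for c, v in values.items()}


def derive_cutoff(ref_acm: dict[str, dict[str, float]]) -> float:
    """Max over reference genes of (max ACM / min ACM) for that gene.

    Since min ACM = 1 by construction this is the largest ACM observed for
    any reference gene — the noise band of a true single-copy sequence.
    """
    if not ref_acm:
        raise ValueError("need at least one reference gene")
    return max(max(acm.values()) / min(acm.values()) for acm in ref_acm.values())


def classify_mobility(acm: dict[str, float], cutoff: float, group1_min: int = 2) -> tuple[int, str]:
    """Count cultivars strictly above the cutoff; group1 when >= ``group1_min``."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    n_above = sum(1 for v in acm.values() if v > cutoff)
    return n_above, ("group1" if n_above >= group1_min else "group2")


def compute_acm_profiles(
    depth: pd.DataFrame,
    rte_ids: list[str],
    ref_gene_ids: list[str],
    cutoff: float | None = None,
    group1_min: int = 2,
) -> tuple[dict[str, AcmProfile], float, list[str]]:
    """Full mobilome analysis from a feature x cultivar mean-depth table.

    ``depth`` is indexed by feature id with one column per cultivar.  When
    ``cutoff`` is None it is derived from the reference genes.  Elements with
    zero depth in any cultivar are excluded (ratio undefined) and returned in
    the third slot as presence/absence variants.
    """
    cultivars = list(depth.columns)
    ref_norm: dict[str, dict[str, float]] = {}
    for gid in ref_gene_ids:
        ref_norm[gid] = {
            c: normalize_coverage(
                float(depth.at[gid, c]), [float(depth.at[g, c]) for g in ref_gene_ids]
            )
            for c in cultivars
        }
    ref_acm = {g: acm_ratios(v) for g, v in ref_norm.items()}
    if cutoff is None:
        cutoff = derive_cutoff(ref_acm)

    profiles: dict[str, AcmProfile] = {}
    absent: list[str] = []
    for rid in rte_ids:
        norm = {
            c: normalize_coverage(
                float(depth.at[rid, c]), [float(depth.at[g, c]) for g in ref_gene_ids]
            )
            for c in cultivars
        }
        try:
            acm = acm_ratios(norm)
        except AcmUndefinedError:
            logger.info("%s absent in >=1 cultivar; excluded from ACM", rid)
            absent.append(rid)
            continue
        n_above, group = classify_mobility(acm, cutoff, group1_min)
        profiles[rid] = AcmProfile(rid, norm, acm, n_above, group)
    return profiles, cutoff, absent


def acm_log2_matrix(profiles: dict[str, AcmProfile]) -> pd.DataFrame:
    """Heatmap-ready log2(ACM) matrix (elements x cultivars)."""
    return pd.DataFrame(
        {rid: {c: np.log2(v) for c, v in p.acm.items()} for rid, p in profiles.items()}
    ).T
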