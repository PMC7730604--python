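"""Per-sample RPKM and breadth of coverage; the expression-calling cascade.

An element is called expressed (exRTE) when it reaches RPKM >= 0.25 in at
least one sample, breadth of coverage >= 60% in at least one sample, and
carries a protein-domain match of at least 50 aa; the expressed set is then
made non-redundant.  Everything else in the candidate catalog forms the
n-exRTE set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from exrte.catalog import RteAnnotation, remove_redundant

logger = logging.getLogger(__name__)


def compute_rpkm(read_count: float, length: int, library_size: float) -> float:
    """Reads per kilobase of feature per million mapped reads.

    rpkm = read_count * 1e9 / (length * library_size)
    """
    if length <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count * 1e9 / (length * library_size)


def covered_fraction(depth: np.ndarray, min_depth: float = 1) -> float:
    """Fraction of positions with depth >= ``min_depth`` (breadth of coverage)."""
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty interval has no breadth of coverage")
    return float(np.count_nonzero(depth >= min_depth) / depth.size)


@dataclass
class SampleEvidence:
    """Expression evidence for one RTE in one sample."""

    read_count: float
    library_size: float
    rpkm: float
    covered_fraction: float


@dataclass
class ExpressionProfile:
    """Per-sample expression evidence and the expressed call for one RTE."""

    rte_id: str
    samples: dict[str, SampleEvidence] = field(default_factory=dict)
    passes_rpkm: bool = False
    passes_coverage: bool = False
    is_expressed: bool = False

    def max_rpkm(self) -> float:
        return max((s.rpkm for s in self.samples.values()), default=0.0)

    def max_breadth(self) -> float:
        return max((s.covered_fraction for s in self.samples.values()), default=0.0)

    def detected_in(self, sample: str, rpkm_min: float = 0.25, cov_min: float = 0.60) -> bool:
        ev = self.samples.get(sample)
        return ev is not None and ev.rpkm >= rpkm_min and ev.covered_fraction >= cov_min


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Materialise a bedGraph (0-based half-open) as per-chromosome depth arrays."""
    depth = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom in depth:
                depth[chrom][int(start) : int(end)] = float(value)
    return depth


def build_profiles(
    rtes: list[RteAnnotation],
    counts: pd.DataFrame,
    library_sizes: dict[str, float],
    depth_by_sample: dict[str, dict[str, np.ndarray]],
    min_depth: float = 1,
    pooled_coverage: bool = False,
) -> dict[str, ExpressionProfile]:
    """Assemble :class:`ExpressionProfile` objects from counts and depth.

    ``counts`` is a long-format table with columns ``rte_id``, ``sample``,
    ``read_count``.  ``depth_by_sample`` maps sample -> per-chromosome depth
    arrays.  With ``pooled_coverage`` breadth is computed on the summed depth
    across samples and stored identically in every sample slot.
    """
    count_map = {
        (row.rte_id, row.sample): float(row.read_count)
        for row in counts.itertuples(index=False)
    }
    samples = list(library_sizes)
    pooled: dict[str, np.ndarray] = {}
    if pooled_coverage:
        for sample in samples:
            for chrom, arr in depth_by_sample[sample].items():
                pooled[chrom] = pooled.get(chrom, 0) + arr

    profiles: dict[str, ExpressionProfile] = {}
    for rte in rtes:
        prof = ExpressionProfile(rte_id=rte.id)
        for sample in samples:
            rc = count_map.get((rte.id, sample), 0.0)
            if pooled_coverage:
                window = pooled.get(rte.chrom, np.zeros(0))[rte.start : rte.end]
            else:
                window = depth_by_sample[sample].get(rte.chrom, np.zeros(0))[
                    rte.start : rte.end
                ]
            breadth = covered_fraction(window, min_depth) if window.size else 0.0
            prof.samples[sample] = SampleEvidence(
                read_count=rc,
                library_size=library_sizes[sample],
                rpkm=compute_rpkm(rc, rte.length, library_sizes[sample]),
                covered_fraction=breadth,
            )
        profiles[rte.id] = prof
    return profiles


def call_expressed(
    profiles: dict[str, ExpressionProfile],
    rtes: list[RteAnnotation],
    seqs: dict[str, str] | None = None,
    rpkm_min: float = 0.25,
    cov_min: float = 0.60,
    min_domain_aa: int = 50,
    dedup_identity: float = 0.95,
    strict_same_sample: bool = False,
) -> tuple[list[str], list[str]]:
    """Apply the expression cascade; return (exRTE ids, n-exRTE ids).

    By default the RPKM and breadth criteria may be met in different samples;
    ``strict_same_sample`` requires one sample satisfying both.  When element
    sequences are supplied, redundancy removal is applied to the expressed
    set and demoted duplicates rejoin the n-exRTE side.
    """
    expressed: list[RteAnnotation] = []
    for rte in rtes:
        prof = profiles.get(rte.id)
        if prof is None:
            logger.warning("RTE %s has no expression profile; treated as silent", rte.id)
            prof = ExpressionProfile(rte_id=rte.id)
            profiles[rte.id] = prof
        if strict_same_sample:
            prof.passes_rpkm = prof.passes_coverage = any(
                ev.rpkm >= rpkm_min and ev.covered_fraction >= cov_min
                for ev in prof.samples.values()
            )
        else:
            prof.passes_rpkm = any(ev.rpkm >= rpkm_min for ev in prof.samples.values())
            prof.passes_coverage = any(
                ev.covered_fraction >= cov_min for ev in prof.samples.values()
            )
        prof.is_expressed = (
            prof.passes_rpkm
            and prof.passes_coverage
            and rte.max_domain_aa >= min_domain_aa
        )
        if prof.is_expressed:
            expressed.append(rte)

    if seqs is not None and len(expressed) > 1:
        kept = remove_redundant(expressed, seqs, identity_cutoff=dedup_identity)
        kept_ids = {r.id for r in kept}
        for rte in expressed:
            if rte.id not in kept_ids:
                profiles[rte.id].is_expressed = False
        expressed = kept

    ex_ids = [r.id for r in expressed]
    ex_set = set(ex_ids)
    nex_ids = [r.id for r in rtes if r.id not in ex_set]
    return ex_ids, nex_ids


def condition_partition(
    profiles: dict[str, ExpressionProfile],
    exrte_ids: list[str],
    sample_labels: dict[str, str],
    rpkm_min: float = 0.25,
    cov_min: float = 0.60,
) -> dict[str, int]:
    """Venn counts of exRTEs detected in non-stressed only / stressed only / both.

    A detection in one sample requires both RPKM and breadth thresholds in
    that sample.  Every sample must carry a ``stressed``/``non-stressed``
    label; exRTEs with no per-sample detection are excluded.
    """
    for sample, label in sample_labels.items():
        if label not in {"stressed", "non-stressed"}:
            raise ValueError(f"sample {sample} has unknown condition label {label!r}")
    counts = {"non-stressed-only": 0, "stressed-only": 0, "both": 0}
    for rte_id in exrte_ids:
        prof = profiles[rte_id]
        detected = {
            sample_labels[s]
            for s in prof.samples
            if s in sample_labels and prof.detected_in(s, rpkm_min, cov_min)
        }
        missing = set(prof.samples) - set(sample_labels)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)}")
        if detected == {"non-stressed"}:
            counts["non-stressed-only"] += 1
        elif detected == {"stressed"}:
            counts["stressed-only"] += 1
        elif detected == {"stressed", "non-stressed"}:
            counts["both"] += 1
    return counts


def profiles_to_frame(profiles: dict[str, ExpressionProfile]) -> pd.DataFrame:
    """Long-format table of per-RTE per-sample evidence and calls."""
    rows = []
    for prof in profiles.values():
        for sample, ev in prof.samples.items():
            rows.append(
                {
                    "rte_id": prof.rte_id,
                    "sample": sample,
                    "read_count": ev.read_count,
                    "library_size": ev.library_size,
                    "rpkm": ev.rpkm,
                    "covered_fraction": ev.covered_fraction,
                    "is_expressed": prof.is_expressed,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rte_id",
            "sample",
            "read_count",
            "library_size",
            "rpkm",
            "covered_fraction",
            "is_expressed",
        ],
    )
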