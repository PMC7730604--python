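"""Insertion dating from 5'/3' LTR divergence.

At integration the two LTRs of an element are identical; substitutions
accumulate independently afterwards, so the Kimura two-parameter (K2P)
distance k between the aligned LTRs, divided by twice the per-site per-year
substitution rate r, estimates the insertion time T = k / (2r).  The default
rate is 1.3e-8 substitutions/site/year and elements younger than 0.5 Myr are
classified as recent.

Note on the distance: the K2P estimator is
    k = -0.5 * ln((1 - 2p - q) * sqrt(1 - 2q)),
with p the transition and q the transversion frequency.  The formula is
sometimes quoted without the leading minus sign; since the log argument is
below 1 for any divergence, the signed form above is the one that yields a
non-negative distance and is used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from exrte.align import global_align

#: Default substitution rate, substitutions per site per year.
DEFAULT_RATE = 1.3e-8

#: Boundary between recent and late insertions, years.
RECENT_BOUNDARY_YEARS = 5e5

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class K2PDomainError(ValueError):
    """Raised when divergence is too saturated for the K2P distance."""


@dataclass
class AgeEstimate:
    """Dating result for one element's LTR pair."""

    rte_id: str
    aligned_columns: int
    p: float
    q: float
    k: float
    r: float
    t_years: float
    recency: str  # "recent" | "late"


def count_substitutions(aligned_a: str, aligned_b: str) -> tuple[float, float, int]:
    """Transition/transversion frequencies from a gapped alignment.

    Gap columns are excluded from both numerator and denominator.  Returns
    (p, q, n) with n the number of gap-free columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    n = transitions = transversions = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable columns in alignment")
    return transitions / n, transversions / n, n


def k2p_distance(p: float, q: float) -> float:
    """Kimura two-parameter distance k = -0.5*ln((1-2p-q)*sqrt(1-2q))."""
    if p < 0 or q < 0:
        raise ValueError("substitution frequencies must be non-negative")
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        raise K2PDomainError(
            f"K2P undefined for p={p:.4g}, q={q:.4g} (saturated divergence)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_time(k: float, r: float = DEFAULT_RATE) -> float:
    """Insertion time in years, T = k / (2r)."""
    if k < 0:
        raise ValueError("distance must be non-negative")
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return k / (2 * r)


def classify_recency(t_years: float, boundary: float = RECENT_BOUNDARY_YEARS) -> str:
    """"recent" for T strictly below the boundary (default 0.5 Myr), else "late"."""
    return "recent" if t_years < boundary else "late"


def date_ltr_pair(
    rte_id: str,
    ltr5: str,
    ltr3: str,
    r: float = DEFAULT_RATE,
    recent_boundary: float = RECENT_BOUNDARY_YEARS,
) -> AgeEstimate:
    """Align an element's LTR pair and date the insertion.

    Raises :class:`K2PDomainError` when divergence is saturated; callers
    record such elements as undatable.
    """
    ga, gb = global_align(ltr5, ltr3)
    p, q, n = count_substitutions(ga, gb)
    k = k2p_distance(p, q)
    t = insertion_time(k, r)
    return AgeEstimate(
        rte_id=rte_id,
        aligned_columns=n,
        p=p,
        q=q,
        k=k,
        r=r,
        t_years=t,
        recency=classify_recency(t, recent_boundary),
    )
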