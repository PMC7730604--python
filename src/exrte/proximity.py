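"""Distance from each RTE to its nearest annotated gene; proximity classes.

Four mutually exclusive categories (precedence insertion > overlapped >
close/distant): *insertion* — the element lies inside a gene; *overlapped* —
the intervals share at least one base without containment of the element;
*close* — gap below 1 kb (adjacent intervals have gap 0 and are close);
*distant* — gap of 1 kb or more.  Strand is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from exrte.catalog import RteAnnotation

CLOSE_GENE_BP = 1000


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass
class GeneProximity:
    rte_id: str
    gene_id: str | None
    distance: float  # bp; 0 when intersecting; inf when no gene on the chromosome
    category: str  # insertion | overlapped | close | distant


def parse_gene_gff(path: str | Path, feature_type: str = "gene") -> list[GeneInterval]:
    """Gene spans (full feature span, 0-based half-open) from a GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gid = feat.attributes.get("ID", [f"{feat.seqid}:{feat.start}-{feat.end}"])[0]
        genes.append(GeneInterval(gid, feat.seqid, feat.start - 1, feat.end))
    return genes


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two 0-based half-open intervals (0 if intersecting)."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end)


def nearest_gene(rte: RteAnnotation, genes: list[GeneInterval]) -> GeneProximity:
    """Nearest gene on the same chromosome and the proximity category.

    Ties on distance are broken by gene start coordinate.  A chromosome with
    no genes yields distance infinity and category distant.
    """
    same_chrom = [g for g in genes if g.chrom == rte.chrom]
    if not same_chrom:
        return GeneProximity(rte.id, None, math.inf, "distant")
    best = min(
        same_chrom, key=lambda g: (_gap(rte.start, rte.end, g.start, g.end), g.start)
    )
    d = _gap(rte.start, rte.end, best.start, best.end)
    if d == 0 and best.start <= rte.start and rte.end <= best.end:
        category = "insertion"
    elif rte.start < best.end and best.start < rte.end:
        category = "overlapped"
    elif d < CLOSE_GENE_BP:
        category = "close"
    else:
        category = "distant"
    return GeneProximity(rte.id, best.gene_id, float(d), category)


def classify_all(
    rtes: list[RteAnnotation],
    genes: list[GeneInterval],
    exrte_ids: set[str] = frozenset(),
) -> pd.DataFrame:
    """Proximity table for all elements with an exRTE/n-exRTE set column."""
    rows = []
    for rte in rtes:
        prox = nearest_gene(rte, genes)
        rows.append(
            {
                "rte_id": rte.id,
                "set": "exRTE" if rte.id in exrte_ids else "n-exRTE",
                "gene_id": prox.gene_id,
                "distance": prox.distance,
                "category": prox.category,
            }
        )
    return pd.DataFrame(
        rows, columns=["rte_id", "set", "gene_id", "distance", "category"]
    )


def category_histogram(table: pd.DataFrame) -> pd.DataFrame:
    """Per-set category counts from a :func:`classify_all` table."""
    return (
        table.groupby(["set", "category"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
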