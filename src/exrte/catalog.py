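"""Parse LTRdigest-style annotation and build the candidate RTE catalog.

The catalog stage mirrors the first funnel of the survey: parse the
annotation, keep elements longer than a minimum length that show similarity
to at least one canonical retroelement protein (GAG, AP, INT, RT, RH), and
collapse highly similar copies so the expressed set is non-redundant.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts
from/to the 1-based inclusive convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from exrte.align import global_identity

logger = logging.getLogger(__name__)

#: Canonical retroelement protein domains.  "RNAseH" is normalised to RH.
CANONICAL_DOMAINS = frozenset({"GAG", "AP", "INT", "RT", "RH"})

_DOMAIN_ALIASES = {
    "RNASEH": "RH",
    "RNASE_H": "RH",
    "RNASE H": "RH",
    "PROT": "AP",
}


def normalize_domain(name: str) -> str:
    """Map a domain label to its canonical symbol (e.g. RNAseH -> RH)."""
    upper = name.strip().upper()
    return _DOMAIN_ALIASES.get(upper, upper)


@dataclass(frozen=True)
class DomainHit:
    """One protein-match: domain symbol, match length in aa, genomic span."""

    domain: str
    aa_length: int
    start: int
    end: int


@dataclass
class RteAnnotation:
    """One annotated LTR retrotransposon.

    Coordinates are 0-based half-open on ``chrom``; ``ltr5``/``ltr3`` are the
    left and right long terminal repeats, both within ``(start, end)``.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    domain_hits: list[DomainHit] = field(default_factory=list)
    superfamily: str | None = None
    clade: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def max_domain_aa(self) -> int:
        """Longest protein-match length in amino acids (0 if none)."""
        return max((h.aa_length for h in self.domain_hits), default=0)

    def domains(self) -> set[str]:
        return {h.domain for h in self.domain_hits}


def _first_attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def parse_ltr_gff(path: str | Path) -> list[RteAnnotation]:
    """Parse an LTRdigest-dialect GFF3 into :class:`RteAnnotation` records.

    Expects ``LTR_retrotransposon`` features with two ``long_terminal_repeat``
    children and zero or more ``protein_match`` children (attributes ``Name``
    = domain, ``aa_length`` = match length).  Children are attached via their
    ``Parent`` attribute.  Elements with a number of LTR children other than
    two are skipped with a warning.  1-based inclusive GFF3 coordinates are
    converted to 0-based half-open.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        logger.warning("annotation %s contains no features", path)
        return []
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot parse GFF3 {path}: {exc}") from exc

    records: list[RteAnnotation] = []
    for elem in db.features_of_type("LTR_retrotransposon", order_by="start"):
        elem_id = _first_attr(elem, "ID") or f"{elem.seqid}:{elem.start}-{elem.end}"
        ltrs = sorted(
            db.children(elem, featuretype="long_terminal_repeat"),
            key=lambda f: f.start,
        )
        if len(ltrs) != 2:
            logger.warning(
                "element %s has %d LTR children (expected 2); skipped",
                elem_id,
                len(ltrs),
            )
            continue
        hits = []
        for pm in db.children(elem, featuretype="protein_match"):
            name = _first_attr(pm, "Name")
            if name is None:
                logger.warning("protein_match without Name under %s; ignored", elem_id)
                continue
            aa = int(_first_attr(pm, "aa_length") or 0)
            hits.append(
                DomainHit(
                    domain=normalize_domain(name),
                    aa_length=aa,
                    start=pm.start - 1,
                    end=pm.end,
                )
            )
        hits.sort(key=lambda h: h.start)
        records.append(
            RteAnnotation(
                id=elem_id,
                chrom=elem.seqid,
                start=elem.start - 1,
                end=elem.end,
                strand=elem.strand if elem.strand in "+-" else "+",
                ltr5=(ltrs[0].start - 1, ltrs[0].end),
                ltr3=(ltrs[1].start - 1, ltrs[1].end),
                domain_hits=hits,
                superfamily=_first_attr(elem, "superfamily"),
                clade=_first_attr(elem, "clade"),
            )
        )
    return records


def filter_candidates(
    rtes: list[RteAnnotation],
    min_len: int = 500,
    required_domains: frozenset[str] | set[str] = CANONICAL_DOMAINS,
) -> list[RteAnnotation]:
    """Keep elements longer than ``min_len`` (strict) with >= 1 canonical
    domain hit.  Order is preserved; the operation is idempotent."""
    required = {normalize_domain(d) for d in required_domains}
    return [
        r
        for r in rtes
        if r.length > min_len and any(h.domain in required for h in r.domain_hits)
    ]


def extract_sequences(
    genome_fasta: str | Path, rtes: list[RteAnnotation]
) -> dict[str, str]:
    """Element sequences from the genome, reverse-complemented for '-' strand."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    seqs: dict[str, str] = {}
    for r in rtes:
        if r.chrom not in genome:
            raise KeyError(f"chromosome {r.chrom} of {r.id} not in FASTA")
        seq = genome[r.chrom][r.start : r.end]
        if r.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        seqs[r.id] = seq
    return seqs


def remove_redundant(
    rtes: list[RteAnnotation],
    seqs: dict[str, str],
    identity_cutoff: float = 0.95,
) -> list[RteAnnotation]:
    """Greedy redundancy removal at a global-identity cutoff.

    Records are processed by descending element length (ties broken by
    chromosome then start coordinate, so the left-most copy survives); a
    record is discarded when its global identity with any already retained
    record exceeds ``identity_cutoff`` (strict).
    """
    ordered = sorted(rtes, key=lambda r: (-r.length, r.chrom, r.start))
    retained: list[RteAnnotation] = []
    for rte in ordered:
        seq = seqs.get(rte.id)
        if seq is None:
            raise KeyError(f"no sequence for {rte.id}")
        if any(global_identity(seq, seqs[kept.id]) > identity_cutoff for kept in retained):
            continue
        retained.append(rte)
    # restore input order for stable downstream tables
    keep_ids = {r.id for r in retained}
    return [r for r in rtes if r.id in keep_ids]
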