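"""ORF prediction, domain labelling, and the CCHC zinc-knuckle (RBM) screen.

ORFs are start-to-stop regions found in all six frames (getorf-style
"-find 1" semantics, minimum 300 nt).  GAG proteins are screened for the
RNA-binding motif CX2CX4HX4C of the nucleocapsid zinc knuckle; the screen's
false-discovery rate is estimated as the motif frequency among non-GAG
proteins.

Domain labelling is pluggable: production runs ingest an external hit table
(ORF id -> domain, BLAST-vs-REXdb style); synthetic runs match planted
peptide tags exactly.  Profile/HMM search itself is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections import Counter

import pandas as pd
from Bio.Seq import Seq

from exrte.catalog import CANONICAL_DOMAINS, RteAnnotation, normalize_domain

_STOPS = {"TAA", "TAG", "TGA"}

#: CCHC zinc knuckle: C, 2 any, C, 4 any, H, 4 any, C (14 residues).
RBM_PATTERN = re.compile(r"C.{2}C.{4}H.{4}C")


@dataclass
class OrfRecord:
    """A predicted ORF within one RTE (coordinates are element-local, nt)."""

    rte_id: str
    orf_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    domain: str = "none"
    rbm_count: int = 0

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass
class GagRbmSummary:
    """Bookkeeping for the RBM screen and its FDR.

    fdr = (non-GAG ORFs carrying the motif) / (all non-GAG ORFs); None when
    there are no non-GAG ORFs.
    """

    n_gag_orfs: int
    n_gag_with_rbm: int
    n_nongag_orfs: int
    n_nongag_with_rbm: int
    fdr: float | None


def scan_rbm(protein: str) -> int:
    """Count non-overlapping left-to-right matches of CX2CX4HX4C."""
    return len(RBM_PATTERN.findall(protein))


def _scan_frames(seq: str, min_nt: int):
    """Yield (start, end, frame) of maximal ATG-to-stop ORFs on one strand.

    An ambiguous codon (containing a non-ACGT base) terminates an open ORF,
    which is reported truncated at that codon.
    """
    n = len(seq)
    for frame in range(3):
        orf_start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            ambiguous = any(b not in "ACGT" for b in codon)
            if ambiguous or codon in _STOPS:
                if orf_start is not None and i - orf_start >= min_nt:
                    yield orf_start, i, frame
                orf_start = None
            elif codon == "ATG" and orf_start is None:
                orf_start = i


def find_orfs(seq: str, min_nt: int = 300, rte_id: str = "") -> list[OrfRecord]:
    """All maximal start-to-stop ORFs of >= ``min_nt`` nt in all six frames.

    The reported span runs from the ATG through the last codon before the
    stop (stop excluded), so nt_length is a multiple of 3.  Reverse-strand
    ORFs are reported in forward coordinates with strand '-'.  The RBM count
    of the translated protein is attached.
    """
    seq = seq.upper()
    records: list[OrfRecord] = []
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for start, end, frame in _scan_frames(s, min_nt):
            protein = str(Seq(s[start:end]).translate())
            if strand == "+":
                span = (start, end)
            else:
                span = (n - end, n - start)
            records.append(
                OrfRecord(
                    rte_id=rte_id,
                    orf_id="",
                    start=span[0],
                    end=span[1],
                    strand=strand,
                    frame=frame,
                    protein=protein,
                    rbm_count=scan_rbm(protein),
                )
            )
    records.sort(key=lambda o: (o.start, o.end, o.strand))
    for i, rec in enumerate(records):
        rec.orf_id = f"{rte_id}_orf{i}" if rte_id else f"orf{i}"
    return records


def label_orfs_with_table(orfs: list[OrfRecord], hits: dict[str, str]) -> None:
    """Assign domains from an external hit table (orf_id -> domain label)."""
    for orf in orfs:
        if orf.orf_id in hits:
            orf.domain = normalize_domain(hits[orf.orf_id])


def label_orfs_by_tags(orfs: list[OrfRecord], tags: dict[str, str]) -> None:
    """Assign domains by exact peptide-tag match (synthetic-data mode)."""
    for orf in orfs:
        for domain, tag in tags.items():
            if tag in orf.protein:
                orf.domain = normalize_domain(domain)
                break


def compute_rbm_fdr(orfs: list[OrfRecord]) -> GagRbmSummary:
    """Estimate the RBM screen FDR from the non-GAG ORF background."""
    gag = [o for o in orfs if o.domain == "GAG"]
    nongag = [o for o in orfs if o.domain != "GAG"]
    n_nongag_rbm = sum(1 for o in nongag if o.rbm_count > 0)
    return GagRbmSummary(
        n_gag_orfs=len(gag),
        n_gag_with_rbm=sum(1 for o in gag if o.rbm_count > 0),
        n_nongag_orfs=len(nongag),
        n_nongag_with_rbm=n_nongag_rbm,
        fdr=(n_nongag_rbm / len(nongag)) if nongag else None,
    )


def gag_rbm_by_set(
    orfs: list[OrfRecord], exrte_ids: set[str]
) -> dict[str, dict[str, int]]:
    """GAG/RBM counts split by expressed vs non-expressed set.

    Both granularities are reported: GAG ORF counts and counts of elements
    possessing at least one GAG ORF (with/without motif).
    """
    out: dict[str, dict[str, int]] = {}
    for name, member in (("exRTE", True), ("n-exRTE", False)):
        sub = [o for o in orfs if (o.rte_id in exrte_ids) == member and o.domain == "GAG"]
        rtes_with_gag = {o.rte_id for o in sub}
        rtes_with_rbm_gag = {o.rte_id for o in sub if o.rbm_count > 0}
        out[name] = {
            "gag_orfs": len(sub),
            "gag_orfs_with_rbm": sum(1 for o in sub if o.rbm_count > 0),
            "rtes_with_gag": len(rtes_with_gag),
            "rtes_with_rbm_gag": len(rtes_with_rbm_gag),
        }
    return out


@dataclass
class DomainSummary:
    """Per-RTE domain sets plus the aggregate combination table."""

    per_rte: pd.DataFrame
    combinations: pd.DataFrame


def summarize_domains(
    rtes: list[RteAnnotation],
    orfs: list[OrfRecord],
    exrte_ids: set[str] = frozenset(),
) -> DomainSummary:
    """Domain set, full-length flag and max ORF length per RTE; combo table.

    An element is full-length when its ORFs together encode all five
    canonical proteins.  The combination table counts domain sets separately
    for the expressed and non-expressed sides.
    """
    by_rte: dict[str, list[OrfRecord]] = {}
    for orf in orfs:
        by_rte.setdefault(orf.rte_id, []).append(orf)

    rows = []
    combo_counter: dict[tuple[str, str], Counter] = {}
    for rte in rtes:
        own = by_rte.get(rte.id, [])
        domains = sorted({o.domain for o in own if o.domain in CANONICAL_DOMAINS})
        combo = "+".join(domains) if domains else "-"
        group = "exRTE" if rte.id in exrte_ids else "n-exRTE"
        combo_counter.setdefault((group, combo), Counter())["n"] += 1
        rows.append(
            {
                "rte_id": rte.id,
                "set": group,
                "domains": ",".join(domains),
                "full_length": set(domains) == set(CANONICAL_DOMAINS),
                "n_orfs": len(own),
                "max_orf_nt": max((o.nt_length for o in own), default=0),
            }
        )
    per_rte = pd.DataFrame(
        rows,
        columns=["rte_id", "set", "domains", "full_length", "n_orfs", "max_orf_nt"],
    )
    combos = pd.DataFrame(
        [
            {"set": group, "combination": combo, "count": counter["n"]}
            for (group, combo), counter in sorted(combo_counter.items())
        ],
        columns=["set", "combination", "count"],
    )
    return DomainSummary(per_rte=per_rte, combinations=combos)
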