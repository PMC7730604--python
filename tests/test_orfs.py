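"""Six-frame ORF finding, domain labelling, and the RBM motif screen."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st_h

from exrte.catalog import DomainHit, RteAnnotation
from exrte.orfs import (
    OrfRecord,
    compute_rbm_fdr,
    find_orfs,
    label_orfs_by_tags,
    scan_rbm,
    summarize_domains,
)
from exrte.simulate import DOMAIN_TAGS

SENSE_CODON = "GCT"  # alanine: cannot form a start or stop


def _orf_seq(n_codons):
    return "ATG" + SENSE_CODON * n_codons + "TAA"


def test_minimum_length_boundary():
    assert len(find_orfs(_orf_seq(99))) == 1  # 300 nt inclusive
    assert find_orfs(_orf_seq(98)) == []  # 297 nt


def test_orf_span_excludes_stop_codon():
    (orf,) = find_orfs(_orf_seq(99))
    assert orf.nt_length == 300
    assert orf.strand == "+" and orf.start == 0 and orf.end == 300
    assert orf.protein == "M" + "A" * 99


def test_reverse_strand_orf_is_reported_in_forward_coordinates():
    fwd = "TTTT" + _orf_seq(99) + "GGGG"
    rev = str(Seq(fwd).reverse_complement())
    (orf,) = find_orfs(rev)
    assert orf.strand == "-"
    assert orf.nt_length == 300
    assert orf.protein == "M" + "A" * 99
    assert (orf.start, orf.end) == (len(rev) - 304, len(rev) - 4)


def test_maximality_uses_first_start_after_previous_stop():
    seq = "ATG" + SENSE_CODON * 10 + "ATG" + SENSE_CODON * 98 + "TAA"
    (orf,) = find_orfs(seq, min_nt=300)
    assert orf.start == 0 and orf.nt_length == len(seq) - 3


def test_ambiguous_codon_truncates_orf():
    seq = "ATG" + SENSE_CODON * 120 + "NNN" + SENSE_CODON * 50 + "TAA"
    lengths = sorted(o.nt_length for o in find_orfs(seq, min_nt=300))
    assert lengths == [363]  # truncated at the ambiguous codon


@settings(deadline=None, max_examples=30)
@given(st_h.text(alphabet="ACGT", min_size=60, max_size=200))
def test_orf_sets_mirror_under_reverse_complement(seq):
    """Strand symmetry: ORFs of a sequence and its reverse complement mirror."""
    fwd = find_orfs(seq, min_nt=30)
    rev = find_orfs(str(Seq(seq).reverse_complement()), min_nt=30)
    n = len(seq)
    mirrored = {(n - o.end, n - o.start, "-" if o.strand == "+" else "+", o.protein) for o in rev}
    assert {(o.start, o.end, o.strand, o.protein) for o in fwd} == mirrored


@pytest.mark.parametrize(
    "protein, count",
    [
        ("CAACAAAAHAAAAC", 1),
        ("MKVLNNN", 0),
        ("CAACAAAAHAAAAC" * 2, 2),  # non-overlapping left-to-right scan
    ],
)
def test_scan_rbm(protein, count):
    assert scan_rbm(protein) == count


@settings(deadline=None, max_examples=50)
@given(st_h.text(alphabet="ADEFGIKLMNPQRSTVWY", max_size=30))
def test_rbm_count_invariant_under_appending_inert_residues(suffix):
    base = "CAACAAAAHAAAAC"
    assert scan_rbm(base + suffix) == scan_rbm(base) == 1


def test_domain_labels_from_planted_tags():
    orfs = [
        OrfRecord("r", "r_orf0", 0, 300, "+", 0, "MAAA" + DOMAIN_TAGS["GAG"] + "AAA"),
        OrfRecord("r", "r_orf1", 400, 700, "+", 0, "MAAA" + DOMAIN_TAGS["RT"] + "AAA"),
        OrfRecord("r", "r_orf2", 800, 1100, "+", 0, "MAAAAAAA"),
    ]
    label_orfs_by_tags(orfs, DOMAIN_TAGS)
    assert [o.domain for o in orfs] == ["GAG", "RT", "none"]


def test_fdr_equals_planted_background_rate():
    """FDR recovers a 10% planted motif rate among 10,000 non-GAG ORFs."""
    rng = np.random.default_rng(42)
    orfs = []
    for i in range(10_000):
        has_motif = rng.random() < 0.10
        orfs.append(
            OrfRecord("r", f"o{i}", 0, 300, "+", 0,
                      protein="X", domain="RT", rbm_count=int(has_motif))
        )
    summary = compute_rbm_fdr(orfs)
    sd = np.sqrt(0.1 * 0.9 / 10_000)
    assert summary.fdr == pytest.approx(0.10, abs=3 * sd)
    assert summary.n_gag_orfs == 0


def test_fdr_undefined_without_nongag_orfs():
    orfs = [OrfRecord("r", "o0", 0, 300, "+", 0, "X", domain="GAG", rbm_count=1)]
    assert compute_rbm_fdr(orfs).fdr is None


def _rte(id):
    return RteAnnotation(
        id=id, chrom="c", start=0, end=5000, strand="+",
        ltr5=(0, 100), ltr3=(4900, 5000),
        domain_hits=[DomainHit("RT", 100, 200, 500)],
    )


def test_summarize_domains_combinations_and_full_length():
    def orf(rte, oid, domain):
        return OrfRecord(rte, oid, 0, 300, "+", 0, "X", domain=domain)

    rtes = [_rte("partial"), _rte("full"), _rte("empty")]
    orfs = [orf("partial", "p0", "GAG"), orf("partial", "p1", "RT"), orf("partial", "p2", "RH")]
    orfs += [orf("full", f"f{i}", d) for i, d in enumerate(["GAG", "AP", "INT", "RT", "RH"])]
    summary = summarize_domains(rtes, orfs, exrte_ids={"full"})
    per = summary.per_rte.set_index("rte_id")
    assert per.loc["partial", "domains"] == "GAG,RH,RT"
    assert not per.loc["partial", "full_length"]
    assert per.loc["full", "full_length"]
    assert per.loc["empty", "domains"] == "" and per.loc["empty", "n_orfs"] == 0
    combos = summary.combinations.set_index(["set", "combination"])["count"]
    assert combos[("exRTE", "AP+GAG+INT+RH+RT")] == 1
    assert combos[("n-exRTE", "-")] == 1


def test_planted_orfs_recovered_with_domains_and_motifs(study_dataset, study_truth_json):
    """On the synthetic genome, every planted ORF is found at its planted
    location with the planted domain tag and RBM count."""
    from exrte.catalog import extract_sequences, parse_ltr_gff
    from exrte.orfs import label_orfs_by_tags

    _, truth, dataset_dir = study_dataset
    rtes = parse_ltr_gff(dataset_dir / "rtes.gff3")[:10]
    seqs = extract_sequences(dataset_dir / "genome.fa", rtes)
    for rte in rtes:
        found = find_orfs(seqs[rte.id], 300, rte_id=rte.id)
        label_orfs_by_tags(found, DOMAIN_TAGS)
        by_span = {(o.start, o.end): o for o in found}
        for planted in study_truth_json["rtes"][rte.id]["orfs"]:
            key = (planted["start"], planted["end"])
            assert key in by_span, f"planted ORF {key} missing in {rte.id}"
            orf = by_span[key]
            assert orf.domain == planted["domain"]
            assert orf.strand == planted["strand"]
            assert orf.rbm_count == planted["rbm_count"]
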