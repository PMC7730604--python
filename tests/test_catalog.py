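"""Annotation parsing, candidate filtering, and redundancy removal."""

import logging

import pytest

from exrte.align import global_identity
from exrte.catalog import (
    DomainHit,
    RteAnnotation,
    filter_candidates,
    parse_ltr_gff,
    remove_redundant,
)

GFF_HEADER = "##gff-version 3\n"


def _write(tmp_path, body, name="test.gff3"):
    path = tmp_path / name
    path.write_text(GFF_HEADER + body)
    return path


def _rte(id, length, domains=(), chrom="chr01", start=0, aa=100):
    return RteAnnotation(
        id=id,
        chrom=chrom,
        start=start,
        end=start + length,
        strand="+",
        ltr5=(start, start + 10),
        ltr3=(start + length - 10, start + length),
        domain_hits=[DomainHit(d, aa, start, start + 30) for d in domains],
    )


def test_roundtrip_recovers_planted_elements(study_dataset, study_truth_json):
    """Parsing the emitted annotation recovers every planted element exactly."""
    _, truth, dataset_dir = study_dataset
    records = {r.id: r for r in parse_ltr_gff(dataset_dir / "rtes.gff3")}
    assert set(records) == set(truth.rtes)
    for rid, t in study_truth_json["rtes"].items():
        rec = records[rid]
        assert (rec.chrom, rec.start, rec.end) == (t["chrom"], t["start"], t["end"])
        assert rec.ltr5 == tuple(t["ltr5"]) and rec.ltr3 == tuple(t["ltr3"])
        assert rec.domains() == {o["domain"] for o in t["orfs"]}
        assert rec.clade == t["clade"] and rec.superfamily == t["superfamily"]


def test_coordinates_convert_to_zero_based_half_open(tmp_path):
    path = _write(
        tmp_path,
        "chr1\tx\tLTR_retrotransposon\t1\t10\t.\t+\t.\tID=e1\n"
        "chr1\tx\tlong_terminal_repeat\t1\t3\t.\t+\t.\tParent=e1\n"
        "chr1\tx\tlong_terminal_repeat\t8\t10\t.\t+\t.\tParent=e1\n",
    )
    (rec,) = parse_ltr_gff(path)
    assert (rec.start, rec.end) == (0, 10)
    assert rec.ltr5 == (0, 3) and rec.ltr3 == (7, 10)
    assert rec.domain_hits == []


def test_element_with_wrong_ltr_count_is_skipped(tmp_path, caplog):
    path = _write(
        tmp_path,
        "chr1\tx\tLTR_retrotransposon\t1\t10\t.\t+\t.\tID=bad\n"
        "chr1\tx\tlong_terminal_repeat\t1\t3\t.\t+\t.\tParent=bad\n",
    )
    with caplog.at_level(logging.WARNING):
        assert parse_ltr_gff(path) == []
    assert "bad" in caplog.text


def test_rnaseh_label_is_normalized_to_rh(tmp_path):
    path = _write(
        tmp_path,
        "chr1\tx\tLTR_retrotransposon\t1\t1000\t.\t+\t.\tID=e1\n"
        "chr1\tx\tlong_terminal_repeat\t1\t100\t.\t+\t.\tParent=e1\n"
        "chr1\tx\tlong_terminal_repeat\t901\t1000\t.\t+\t.\tParent=e1\n"
        "chr1\tx\tprotein_match\t200\t400\t.\t+\t.\tParent=e1;Name=RNAseH;aa_length=67\n",
    )
    (rec,) = parse_ltr_gff(path)
    assert rec.domains() == {"RH"}
    assert rec.max_domain_aa == 67


@pytest.mark.parametrize(
    "length, domains, kept",
    [
        (501, ("GAG",), True),  # strictly > 500 with one canonical hit
        (2000, (), False),  # no domain evidence
        (500, ("RT",), False),  # boundary excluded
    ],
)
def test_filter_candidates_boundaries(length, domains, kept):
    result = filter_candidates([_rte("x", length, domains)])
    assert bool(result) is kept


def test_filter_candidates_is_idempotent():
    rtes = [_rte("a", 501, ("GAG",)), _rte("b", 400, ("RT",)), _rte("c", 600, ())]
    once = filter_candidates(rtes)
    assert filter_candidates(once) == once


def test_remove_redundant_identical_pair_keeps_leftmost():
    seq = "ACGTTGCA" * 50
    a = _rte("a", 400, ("RT",), start=0)
    b = _rte("b", 400, ("RT",), start=10_000)
    kept = remove_redundant([a, b], {"a": seq, "b": seq})
    assert [r.id for r in kept] == ["a"]


def test_remove_redundant_dissimilar_pair_keeps_both():
    import numpy as np

    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    s1 = "".join(bases[rng.integers(0, 4, 300)])
    s2 = "".join(bases[rng.integers(0, 4, 300)])
    kept = remove_redundant(
        [_rte("a", 300), _rte("b", 300, start=5000)], {"a": s1, "b": s2}
    )
    assert len(kept) == 2


def test_remove_redundant_greedy_chain():
    """A~B and B~C above the cutoff, A~C below: greedy from the front keeps A and C."""
    base = list("ACGTTGCAAGGTCCAT" * 20)  # 320 bp
    b = base.copy()
    for i in (5, 100, 200):  # 3 substitutions: ~99% identity to A
        b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
    c = b.copy()
    for i in range(10, 10 + 14 * 11, 11):  # 14 more: ~95.6% to B, ~94.7% to A
        c[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[c[i]]
    seqs = {"a": "".join(base), "b": "".join(b), "c": "".join(c)}
    assert global_identity(seqs["a"], seqs["b"]) > 0.95
    assert global_identity(seqs["b"], seqs["c"]) > 0.95
    assert global_identity(seqs["a"], seqs["c"]) <= 0.95
    rtes = [_rte("a", 320, start=0), _rte("b", 320, start=1000), _rte("c", 320, start=2000)]
    kept = remove_redundant(rtes, seqs)
    assert [r.id for r in kept] == ["a", "c"]


def test_retained_set_has_pairwise_identity_below_cutoff(study_dataset):
    """Invariant: after dedup no retained pair exceeds the identity cutoff."""
    import itertools

    from exrte.catalog import extract_sequences

    _, truth, dataset_dir = study_dataset
    rtes = parse_ltr_gff(dataset_dir / "rtes.gff3")[:8]
    seqs = extract_sequences(dataset_dir / "genome.fa", rtes)
    kept = remove_redundant(rtes, seqs)
    for r1, r2 in itertools.combinations(kept, 2):
        assert global_identity(seqs[r1.id], seqs[r2.id]) <= 0.95
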