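"""Global pairwise nucleotide alignment and identity.

A single scoring scheme (match +1, mismatch -1, linear gap -2) is shared by
the redundancy filter and the LTR-pair dating step so that both see the same
alignments.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def global_align(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences; return the gapped strings.

    Needleman-Wunsch with match +1, mismatch -1, linear gaps -2.  Among
    co-optimal alignments the aligner's first traceback is taken, which is
    deterministic for a given pair of inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    alignment = _aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal global alignment.

    identity = matches / alignment columns (gap columns count in the
    denominator).  The pair is ordered canonically before aligning so the
    result is symmetric in its arguments even when co-optimal alignments
    with different column counts exist.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of empty sequences")
    if b < a:
        a, b = b, a
    ga, gb = global_align(a, b)
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return matches / len(ga)
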