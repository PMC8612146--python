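"""Protein alignment engine and E-value statistics.

Local (Smith-Waterman) and global (Needleman-Wunsch) alignments use
BLOSUM62 with BLAST-style affine gaps: a gap of length L costs
``11 + L`` (existence 11, extension 1 per residue).  Significance of local
scores follows Karlin-Altschul statistics with the gapped BLOSUM62
constants lambda = 0.267, K = 0.041:

    S' = (lambda * S - ln K) / ln 2        (bit score)
    E  = m * n * 2 ** (-S')                (expected chance hits)

where m is the query length and n the search-space length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: Gapped Karlin-Altschul constants for BLOSUM62 with gap costs 11/1.
LAMBDA = 0.267
K = 0.041

GAP_OPEN = 11  # cost of opening a gap (gap of length L costs GAP_OPEN + L)
GAP_EXTEND = 1

BLOSUM62 = substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode=mode,
        # biopython charges open_gap_score at the first gapped position,
        # so open=-(GAP_OPEN+GAP_EXTEND), extend=-GAP_EXTEND gives 11 + L.
        open_gap_score=-(GAP_OPEN + GAP_EXTEND),
        extend_gap_score=-GAP_EXTEND,
    )
    aligner.substitution_matrix = BLOSUM62
    return aligner


def local_score(target: str, query: str) -> float:
    """Smith-Waterman score (fast path: no traceback)."""
    return _aligner("local").score(target, query)


def local_align(target: str, query: str) -> Align.Alignment:
    """Best local alignment; deterministic first-optimal traceback."""
    return _aligner("local").align(target, query)[0]


def global_score(target: str, query: str) -> float:
    return _aligner("global").score(target, query)


def global_align(target: str, query: str) -> Align.Alignment:
    return _aligner("global").align(target, query)[0]


def alignment_identity(aln: Align.Alignment) -> float:
    """Identical residue pairs / alignment length including gap columns."""
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if length == 0:
        return 0.0
    return counts.identities / length


def global_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) identity between two proteins.

    The denominator is the full alignment length including gap columns
    (terminal gaps count), matching the SDT convention of scoring gaps
    as mismatches.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    if a == b:
        return 1.0
    # align the lexicographically smaller sequence first so that
    # identity(a, b) == identity(b, a) even under traceback ties
    x, y = (a, b) if a <= b else (b, a)
    return alignment_identity(global_align(x, y))


@dataclass(frozen=True)
class ScoredHit:
    bitscore: float
    evalue: float


def karlin_altschul_evalue(raw_score: float, m: int, n: int) -> tuple[float, float]:
    """Bit score and E-value of a local alignment raw score.

    ``m`` is the query length (residues) and ``n`` the search-space length
    (residues or nucleotides, depending on the search).  E is linear in
    both and monotone decreasing in the raw score.
    """
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    bitscore = (LAMBDA * raw_score - math.log(K)) / math.log(2)
    evalue = m * n * 2.0 ** (-bitscore)
    return bitscore, evalue
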