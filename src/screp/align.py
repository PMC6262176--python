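"""Exact pairwise alignment and alignment statistics.

This module is the pipeline's stand-in for a ``blastp`` search: optimal
Smith-Waterman local (and Needleman-Wunsch global) alignment under the
BLOSUM62 substitution matrix with affine gap costs, plus Karlin-Altschul
bit-score / E-value statistics.  Because the dynamic programme is exact,
scores are deterministic and never lower than a heuristic search would
report; the pipeline's raw-score and bit-score thresholds are applied to
these exact scores.

The affine gap model charges ``gap_open + g * gap_extend`` for a gap of
length ``g`` (BLAST convention: the first gap residue costs
``gap_open + gap_extend``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "local_align",
    "global_align",
    "evalue",
    "load_matrix",
]

# Gapped BLOSUM62 11/1 Karlin-Altschul constants as published by NCBI BLAST.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

# Residues absent from the BLOSUM62 alphabet are scored as X (fully
# ambiguous).  U (selenocysteine) is deliberately NOT treated as cysteine.
_TO_X = str.maketrans({"U": "X", "O": "X", "J": "X"})


def load_matrix(path) -> substitution_matrices.Array:
    """Load a substitution matrix from an NCBI-format text file."""
    return substitution_matrices.read(str(path))


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants.

    Defaults are the BLAST protein defaults: BLOSUM62 with gap open 11 /
    extend 1, and the published gapped Karlin-Altschul constants for that
    combination (lambda = 0.267, K = 0.041).  ``lambda_`` and ``k_const``
    are only meaningful for the parameter set they were estimated for; if
    you swap the matrix or penalties, supply matching constants.
    """

    matrix: substitution_matrices.Array = field(
        default_factory=lambda: substitution_matrices.load("BLOSUM62")
    )
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = DEFAULT_LAMBDA
    k_const: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.gap_extend < 1 or self.gap_open < self.gap_extend:
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        self._aligners: dict[str, Align.PairwiseAligner] = {}

    def score_pair(self, a: str, b: str) -> float:
        """Substitution score of residues ``a`` vs ``b``."""
        return float(self.matrix[a.translate(_TO_X), b.translate(_TO_X)])

    def self_score(self, seq: str) -> int:
        """Sum of diagonal matrix entries: the gapless self-alignment score."""
        return int(sum(self.score_pair(c, c) for c in seq))

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        """A cached PairwiseAligner configured for ``mode`` (local/global)."""
        if mode not in self._aligners:
            a = Align.PairwiseAligner()
            a.substitution_matrix = self.matrix
            # Biopython's open_gap_score applies to the first gap residue.
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -self.gap_extend
            a.mode = mode
            self._aligners[mode] = a
        return self._aligners[mode]


@dataclass(frozen=True)
class LocalAlignment:
    """One scored pairwise alignment.

    Coordinates are 0-based half-open on the original (ungapped)
    sequences.  ``identity_pct`` counts identical aligned columns over the
    full alignment length, gap columns included.  ``gap_openings`` counts
    contiguous gap runs in either row.
    """

    raw_score: int
    bit_score: float
    evalue: float
    identity_pct: float
    n_identical: int
    length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    gap_openings: int
    query_id: str = "query"
    subject_id: str = "subject"

    @property
    def is_empty(self) -> bool:
        return self.length == 0


def _sanitize(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty {label} sequence")
    return seq.upper().translate(_TO_X)


def _rows_stats(row_q: str, row_s: str) -> tuple[int, int]:
    """(identical columns, gap openings) of a pair of gapped rows."""
    ident = sum(1 for x, y in zip(row_q, row_s) if x == y and x != "-")
    opens = 0
    for row in (row_q, row_s):
        in_gap = False
        for ch in row:
            if ch == "-":
                if not in_gap:
                    opens += 1
                in_gap = True
            else:
                in_gap = False
    return ident, opens


def _empty(query: str, subject: str, scheme: ScoringScheme,
           query_id: str, subject_id: str) -> LocalAlignment:
    bits, ev = evalue(0, len(query), len(subject), scheme)
    return LocalAlignment(0, bits, ev, 0.0, 0, 0, 0, 0, 0, 0, 0,
                          query_id, subject_id)


def local_align(query: str, subject: str,
                scheme: Optional[ScoringScheme] = None,
                query_id: str = "query",
                subject_id: str = "subject") -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of ``query`` vs ``subject``.

    A score-0 result is reported as an empty alignment (no positive-scoring
    cell exists).  Ties between co-optimal tracebacks are broken by the
    aligner's deterministic first-traceback order, so repeated calls are
    bit-reproducible.
    """
    scheme = scheme or ScoringScheme()
    q = _sanitize(query, "query")
    s = _sanitize(subject, "subject")
    alignments = scheme.aligner("local").align(q, s)
    if alignments.score <= 0:
        return _empty(q, s, scheme, query_id, subject_id)
    best = alignments[0]
    raw = int(round(best.score))
    ident, opens = _rows_stats(str(best[0]), str(best[1]))
    length = best.length
    qblocks, sblocks = best.aligned
    bits, ev = evalue(raw, len(q), len(s), scheme)
    return LocalAlignment(
        raw_score=raw, bit_score=bits, evalue=ev,
        identity_pct=100.0 * ident / length, n_identical=ident,
        length=length,
        q_start=int(qblocks[0][0]), q_end=int(qblocks[-1][1]),
        s_start=int(sblocks[0][0]), s_end=int(sblocks[-1][1]),
        gap_openings=opens, query_id=query_id, subject_id=subject_id,
    )


def global_align(a: str, b: str,
                 scheme: Optional[ScoringScheme] = None,
                 query_id: str = "query",
                 subject_id: str = "subject") -> LocalAlignment:
    """Optimal Needleman-Wunsch global alignment under the same gap model.

    The result spans both full sequences; ``identity_pct`` is computed over
    the full alignment length including terminal gap columns.  ``raw_score``
    may be negative for dissimilar sequences.
    """
    scheme = scheme or ScoringScheme()
    qa = _sanitize(a, "first")
    qb = _sanitize(b, "second")
    best = scheme.aligner("global").align(qa, qb)[0]
    raw = int(round(best.score))
    ident, opens = _rows_stats(str(best[0]), str(best[1]))
    length = best.length
    bits, ev = evalue(max(raw, 0), len(qa), len(qb), scheme)
    return LocalAlignment(
        raw_score=raw, bit_score=bits, evalue=ev,
        identity_pct=100.0 * ident / length, n_identical=ident,
        length=length,
        q_start=0, q_end=len(qa), s_start=0, s_end=len(qb),
        gap_openings=opens, query_id=query_id, subject_id=subject_id,
    )


def evalue(raw_score: int, m: int, n: int,
           scheme: Optional[ScoringScheme] = None) -> tuple[float, float]:
    """Karlin-Altschul statistics for a raw alignment score.

    bit_score = (lambda * S - ln K) / ln 2
    evalue    = m * n * 2 ** (-bit_score)

    ``m`` is the query length and ``n`` the total residue count of the
    search space.  No edge-effect length correction is applied.
    """
    scheme = scheme or ScoringScheme()
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    bits = (scheme.lambda_ * raw_score - math.log(scheme.k_const)) / math.log(2)
    ev = float(m) * float(n) * 2.0 ** (-bits)
    return bits, ev
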