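"""Seeded local nucleotide alignment shared by NAT discovery and the
conservation scan.

The aligner is a drop-in, desk-scale replacement for a BLASTN search: an
exact shared word of ``word_size`` nt is required as a seed, after which the
optimal affine local alignment is computed (match +1, mismatch -2, gap of
length k costs 5 + 2k).  No E-value statistics are computed; a raw score
threshold stands in for them.  ``N`` never matches anything, including ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .core_model import revcomp

DEFAULT_WORD_SIZE = 11
DEFAULT_MIN_SCORE = 50
MATCH = 1
MISMATCH = -2
GAP_OPEN = 5   # charged once per gap, on top of the per-nt extension
GAP_EXTEND = 2


def _make_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "N" or b == "N":
                matrix[a, b] = mismatch
            else:
                matrix[a, b] = match if a == b else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap nt and
    # extend_gap_score for each further nt; open+extend here yields 5+2k.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class LocalAlignment:
    """One local alignment, coordinates on each sequence's own 5'->3' axis."""

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_columns: int
    n_identical: int
    q_blocks: list[tuple[int, int]] = field(default_factory=list)
    s_blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_columns if self.n_columns else 0.0

    @property
    def length(self) -> int:
        """Alignment length in columns (gaps included), as BLAST reports it."""
        return self.n_columns


def _has_shared_word(a: str, b: str, w: int) -> bool:
    if len(a) < w or len(b) < w:
        return False
    words = {a[i : i + w] for i in range(len(a) - w + 1) if "N" not in a[i : i + w]}
    return any(b[i : i + w] in words for i in range(len(b) - w + 1))


def _summarize(aln, query: str, subject: str) -> LocalAlignment:
    qb, sb = (
        [(int(s), int(e)) for s, e in aln.aligned[0]],
        [(int(s), int(e)) for s, e in aln.aligned[1]],
    )
    n_id = 0
    n_aligned = 0
    for (qs, qe), (ss, _se) in zip(qb, sb):
        for k in range(qe - qs):
            cq, cs = query[qs + k], subject[ss + k]
            if cq == cs and cq != "N":
                n_id += 1
        n_aligned += qe - qs
    gap_cols = 0
    for i in range(1, len(qb)):
        gap_cols += (qb[i][0] - qb[i - 1][1]) + (sb[i][0] - sb[i - 1][1])
    return LocalAlignment(
        score=float(aln.score),
        q_start=qb[0][0],
        q_end=qb[-1][1],
        s_start=sb[0][0],
        s_end=sb[-1][1],
        n_columns=n_aligned + gap_cols,
        n_identical=n_id,
        q_blocks=qb,
        s_blocks=sb,
    )


def seeded_local_align(
    query: str,
    subject: str,
    word_size: int = DEFAULT_WORD_SIZE,
    min_score: float = DEFAULT_MIN_SCORE,
    max_hits: int = 3,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> list[LocalAlignment]:
    """Best local alignments of ``query`` against ``subject`` (same strand).

    Requires an exact shared ``word_size``-mer as a seed; without one the
    result is empty.  Up to ``max_hits`` non-overlapping (on the query)
    alignments with score >= ``min_score`` are returned, best first.
    """
    query, subject = query.upper(), subject.upper()
    if not _has_shared_word(query, subject, word_size):
        return []
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    hits: list[LocalAlignment] = []
    masked = query
    for _ in range(max_hits):
        if not _has_shared_word(masked, subject, word_size):
            break
        alns = aligner.align(masked, subject)
        if len(alns) == 0 or alns[0].score < min_score:
            break
        hit = _summarize(alns[0], masked, subject)
        hits.append(hit)
        masked = masked[: hit.q_start] + "N" * (hit.q_end - hit.q_start) + masked[hit.q_end :]
    return hits


def complement_align(
    query: str,
    subject: str,
    word_size: int = DEFAULT_WORD_SIZE,
    min_score: float = DEFAULT_MIN_SCORE,
    max_hits: int = 3,
) -> list[LocalAlignment]:
    """Local alignments of ``query`` against revcomp(``subject``).

    Subject coordinates in the result are mapped back to the subject's own
    5'->3' axis, so an alignment describes an antisense (complementary)
    region between the two transcripts.
    """
    rc = revcomp(subject.upper())
    hits = seeded_local_align(query, rc, word_size=word_size, min_score=min_score, max_hits=max_hits)
    n = len(subject)
    for h in hits:
        h.s_start, h.s_end = n - h.s_end, n - h.s_start
        h.s_blocks = [(n - e, n - s) for s, e in reversed(h.s_blocks)]
    return hits
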