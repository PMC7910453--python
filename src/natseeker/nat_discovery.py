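"""Identification of candidate cis- and trans-NAT pairs.

A NAT (natural antisense transcript) is a noncoding-candidate transcript
complementary to a protein-coding sense transcript (ST).  cis-NATs overlap
their ST on the opposite strand of the same locus; trans-NATs come from a
different locus and are detected by reverse-complement local alignment
followed by an RNA-RNA annealing check.

Candidate conditions (either suffices):
  (1) total complementary-region length exceeds 50% of at least one of the
      two transcripts' spliced lengths;
  (2) a single consecutive complementary region is 100 bp or longer.

trans candidates must additionally anneal: the duplexed span must coincide
with the complementary region, cover more than 80% of it, and contain no
internal bubble of 10% of the region or more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from . import alignment
from .core_model import ExpressionMatrix, Transcript

logger = logging.getLogger(__name__)

DEFAULT_FPKM_CUTOFF = 1.0
DEFAULT_MIN_REGION = 100
DEFAULT_FRAC_CONDITION = 0.5
DEFAULT_ANNEAL_FRAC = 0.8
DEFAULT_BUBBLE_FRAC = 0.1
COINCIDENT_SLACK = 5  # nt of slack at each end of the annealed span


@dataclass
class ComplementaryRegion:
    """An antisense-matching segment between an ST and a NAT.

    Intervals are 0-based half-open on each transcript's own spliced
    (5'->3') coordinates.  For cis pairs the region is a genomic exon
    overlap and identity is 1 by construction; for trans pairs it comes
    from a local alignment.
    """

    st_interval: tuple[int, int]
    nat_interval: tuple[int, int]
    length: int
    identity: float
    source: str  # "genomic_overlap" | "alignment"
    genomic_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("complementary region must have length >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.source == "genomic_overlap" and self.identity != 1.0:
            raise ValueError("genomic overlap regions have identity 1 by construction")


@dataclass
class AnnealingResult:
    """Outcome of the RNA-RNA duplex check on a complementary region.

    ``pass_`` is true iff the annealed span is coincident with the
    complementary region, covers more than 80% of it, and every internal
    bubble is shorter than 10% of the region.
    """

    annealed_len: int
    comp_len: int
    bubbles: list[tuple[int, int]] = field(default_factory=list)  # (offset, length)
    coincident: bool = True
    annealed_fraction: float = field(init=False)
    max_bubble_fraction: float = field(init=False)
    pass_: bool = field(init=False)

    def __post_init__(self):
        if self.comp_len <= 0:
            raise ValueError("comp_len must be positive")
        self.annealed_fraction = self.annealed_len / self.comp_len
        max_bubble = max((b for _, b in self.bubbles), default=0)
        self.max_bubble_fraction = max_bubble / self.comp_len
        self.pass_ = (
            self.coincident
            and self.annealed_fraction > DEFAULT_ANNEAL_FRAC
            and self.max_bubble_fraction < DEFAULT_BUBBLE_FRAC
        )


@dataclass
class SATPair:
    """An ST-NAT pairing with its complementary regions and classifications."""

    st_id: str
    nat_id: str
    category: str  # "cis" | "trans"
    regions: list[ComplementaryRegion]
    st_len: int
    nat_len: int
    annealing: AnnealingResult | None = None
    positional_type: str | None = None
    relationship: str | None = None
    coexpression_r: float | None = None

    @property
    def total_overlap(self) -> int:
        return sum(r.length for r in self.regions)

    @property
    def max_region(self) -> int:
        return max((r.length for r in self.regions), default=0)


# ---------------------------------------------------------------------------
# Expression filter

def filter_expressed(
    transcripts: Sequence[Transcript],
    expr: ExpressionMatrix,
    cutoff: float = DEFAULT_FPKM_CUTOFF,
) -> list[Transcript]:
    """Keep transcripts with mean FPKM >= cutoff in at least one tissue."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    means = expr.tissue_means()
    kept, n_absent = [], 0
    for t in transcripts:
        if t.id not in means.index:
            n_absent += 1
            continue
        if (means.loc[t.id] >= cutoff).any():
            kept.append(t)
    if n_absent:
        logger.warning("filter_expressed: %d transcripts absent from the matrix dropped", n_absent)
    return kept


# ---------------------------------------------------------------------------
# cis candidates: opposite-strand exon overlap at the same locus

def _intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two sorted, non-overlapping interval lists."""
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _single_spliced_interval(t: Transcript, start: int, end: int) -> tuple[int, int]:
    ivs = t.spliced_intervals(start, end)
    if len(ivs) != 1 or (ivs[0][1] - ivs[0][0]) != (end - start):
        raise ValueError(
            f"genomic interval [{start},{end}) is not a contiguous exonic block of {t.id}"
        )
    return ivs[0]


def find_cis_candidates(transcripts: Sequence[Transcript]) -> list[SATPair]:
    """All (coding ST, noncoding-candidate NAT) couples on the same contig,
    opposite strands, with at least 1 bp of exon-level overlap."""
    by_contig: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_contig.setdefault(t.chrom, []).append(t)
    pairs = []
    for _contig, ts in sorted(by_contig.items()):
        coding = [t for t in ts if t.biotype == "coding"]
        unknown = [t for t in ts if t.biotype == "unknown"]
        for st in coding:
            for nat in unknown:
                if st.strand == nat.strand:
                    continue
                if st.end <= nat.start or nat.end <= st.start:
                    continue
                hits = _intersect_intervals(st.exons, nat.exons)
                if not hits:
                    continue
                regions = [
                    ComplementaryRegion(
                        st_interval=_single_spliced_interval(st, s, e),
                        nat_interval=_single_spliced_interval(nat, s, e),
                        length=e - s,
                        identity=1.0,
                        source="genomic_overlap",
                        genomic_interval=(s, e),
                    )
                    for s, e in hits
                ]
                pairs.append(
                    SATPair(
                        st_id=st.id,
                        nat_id=nat.id,
                        category="cis",
                        regions=regions,
                        st_len=st.length,
                        nat_len=nat.length,
                    )
                )
    return pairs


def candidate_condition(
    pair: SATPair,
    min_region: int = DEFAULT_MIN_REGION,
    frac: float = DEFAULT_FRAC_CONDITION,
) -> bool:
    """True iff the pair satisfies either NAT candidate condition."""
    if not pair.regions:
        return False
    total = pair.total_overlap
    longer_than_half = total > frac * pair.st_len or total > frac * pair.nat_len
    return longer_than_half or pair.max_region >= min_region


# ---------------------------------------------------------------------------
# trans complementarity: alignment + annealing

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# Watson-Crick plus G:U wobble; N never pairs.
_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")]:
    _PAIRABLE[_CODE[_a], _CODE[_b]] = True


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.uint8)


@njit(cache=False)
def _anneal_fill(s: np.ndarray, t_rev: np.ndarray, pairable: np.ndarray) -> np.ndarray:
    n, m = len(s), len(t_rev)
    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        for k in range(1, m + 1):
            best = dp[i - 1, k]
            if dp[i, k - 1] > best:
                best = dp[i, k - 1]
            if pairable[s[i - 1], t_rev[k - 1]]:
                v = dp[i - 1, k - 1] + 1
                if v > best:
                    best = v
            dp[i, k] = best
    return dp


def _max_pairing(s_seq: str, t_seq: str) -> list[tuple[int, int]]:
    """Maximum non-crossing antiparallel pairing between two strands.

    Returns pairs (i, j): position i on s_seq pairs position j on t_seq,
    i ascending, j descending.  Tie-break: the traceback prefers pairing,
    then consuming s, giving a deterministic leftmost layout.
    """
    s = encode(s_seq)
    t = encode(t_seq)
    t_rev = t[::-1].copy()
    dp = _anneal_fill(s, t_rev, _PAIRABLE)
    pairs = []
    i, k = len(s), len(t_rev)
    while i > 0 and k > 0:
        if _PAIRABLE[s[i - 1], t_rev[k - 1]] and dp[i, k] == dp[i - 1, k - 1] + 1:
            pairs.append((i - 1, len(t) - 1 - (k - 1)))
            i, k = i - 1, k - 1
        elif dp[i, k] == dp[i - 1, k]:
            i -= 1
        else:
            k -= 1
    pairs.reverse()
    return pairs


def assess_annealing(
    st_region_seq: str,
    nat_region_seq: str,
    slack: int = COINCIDENT_SLACK,
) -> AnnealingResult:
    """Duplex the complementary region by base-pair maximization.

    Pairing allows Watson-Crick and G:U wobble pairs, no pseudoknots and no
    intra-strand pairing.  Bubbles are maximal unpaired runs internal to the
    annealed span (the larger of the two strands' gaps between consecutive
    pairs).  The result is invariant to swapping the ST and NAT roles: the
    two sequences are canonicalized (sorted) before the DP.
    """
    a, b = sorted([st_region_seq.upper(), nat_region_seq.upper()])
    pairs = _max_pairing(a, b)
    comp_len = max(len(a), len(b))
    if not pairs:
        return AnnealingResult(annealed_len=0, comp_len=comp_len, bubbles=[], coincident=False)
    bubbles = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        gap = max(i2 - i1 - 1, j1 - j2 - 1)
        if gap > 0:
            bubbles.append((i1 + 1, gap))
    i_first, j_first = pairs[0]
    i_last, j_last = pairs[-1]
    coincident = (
        i_first <= slack
        and (len(a) - 1 - i_last) <= slack
        and (len(b) - 1 - j_first) <= slack
        and j_last <= slack
    )
    return AnnealingResult(
        annealed_len=len(pairs), comp_len=comp_len, bubbles=bubbles, coincident=coincident
    )


def find_trans_candidates(
    transcripts: Sequence[Transcript],
    word_size: int = alignment.DEFAULT_WORD_SIZE,
    min_score: float = alignment.DEFAULT_MIN_SCORE,
) -> list[SATPair]:
    """Complementary-alignment candidates between non-overlapping loci."""
    coding = [t for t in transcripts if t.biotype == "coding"]
    unknown = [t for t in transcripts if t.biotype == "unknown"]
    pairs = []
    for st in coding:
        for nat in unknown:
            if st.chrom == nat.chrom and not (st.end <= nat.start or nat.end <= st.start):
                continue  # genomic overlap -> cis territory
            hits = alignment.complement_align(
                st.spliced_seq, nat.spliced_seq, word_size=word_size, min_score=min_score
            )
            if not hits:
                continue
            regions = [
                ComplementaryRegion(
                    st_interval=(h.q_start, h.q_end),
                    nat_interval=(h.s_start, h.s_end),
                    length=max(h.q_end - h.q_start, h.s_end - h.s_start),
                    identity=h.identity,
                    source="alignment",
                )
                for h in hits
            ]
            pairs.append(
                SATPair(
                    st_id=st.id,
                    nat_id=nat.id,
                    category="trans",
                    regions=regions,
                    st_len=st.length,
                    nat_len=nat.length,
                )
            )
    return pairs


def anneal_pair(pair: SATPair, transcripts: Mapping[str, Transcript]) -> AnnealingResult:
    """Run the annealing check on the pair's largest complementary region."""
    if pair.category != "trans":
        raise ValueError("annealing applies to trans pairs only")
    region = max(pair.regions, key=lambda r: r.length)
    st = transcripts[pair.st_id]
    nat = transcripts[pair.nat_id]
    st_seq = st.spliced_seq[region.st_interval[0] : region.st_interval[1]]
    nat_seq = nat.spliced_seq[region.nat_interval[0] : region.nat_interval[1]]
    result = assess_annealing(st_seq, nat_seq)
    pair.annealing = result
    return result


# ---------------------------------------------------------------------------
# Composition

def discover(
    transcripts: Sequence[Transcript],
    expr: ExpressionMatrix | None = None,
    fpkm_cutoff: float = DEFAULT_FPKM_CUTOFF,
    min_region: int = DEFAULT_MIN_REGION,
    frac: float = DEFAULT_FRAC_CONDITION,
    word_size: int = alignment.DEFAULT_WORD_SIZE,
    min_score: float = alignment.DEFAULT_MIN_SCORE,
) -> list[SATPair]:
    """Full discovery pass: expression filter, then cis and trans candidates.

    cis pairs bypass the annealing check (a genomic overlap is perfectly
    complementary by construction); trans pairs must anneal.
    """
    ts = list(transcripts)
    if expr is not None:
        ts = filter_expressed(ts, expr, cutoff=fpkm_cutoff)
    by_id = {t.id: t for t in ts}
    cis = [p for p in find_cis_candidates(ts) if candidate_condition(p, min_region, frac)]
    trans = []
    for p in find_trans_candidates(ts, word_size=word_size, min_score=min_score):
        if not candidate_condition(p, min_region, frac):
            continue
        if anneal_pair(p, by_id).pass_:
            trans.append(p)
    return cis + trans
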