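"""miRNA interaction layer.

Two questions are asked of a SAT pair:

* does the ST carry a miRNA target site inside the region overlapped by its
  NAT (so that duplex formation could mask the site), and
* could the NAT itself be a miRNA precursor (a pri-miRNA), i.e. does the
  region around a mature-miRNA match fold into a stem-loop meeting plant
  miRNA annotation criteria?

Target scanning uses a gapless sliding-window alignment of the reverse
complement of the mature miRNA along the ST, with a psRNATarget-style
penalty (mismatch 1, G:U wobble 0.5, gap 2, doubled at miRNA positions
2-13; expectation cutoff 5).  Folding is Nussinov base-pair maximization
(Watson-Crick + G:U, minimum hairpin loop 3 nt, no pseudoknots), which is
sufficient because the precursor criteria depend only on pairing topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .core_model import Transcript, normalize_seq, to_rna
from .nat_discovery import _PAIRABLE, encode

EXPECTATION_CUTOFF = 5.0
SEED_REGION = (2, 13)  # miRNA positions with doubled penalty, 1-based inclusive
CENTER_REGION = (9, 11)  # mismatch here -> translational inhibition call
MIN_LOOP = 3
MAX_FOLD_LEN = 400
DEFAULT_FLANK = 150

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0  # part of the scheme; the scan itself is gapless

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass
class MirnaHit:
    mirna_id: str
    st_id: str
    site_interval: tuple[int, int]  # on ST spliced coordinates
    expectation: float
    inhibition: str  # cleavage | translation
    in_overlap: bool
    aligned_mirna: str = ""  # RNA alphabet, 5'->3'
    aligned_st: str = ""     # RNA alphabet, 5'->3'


@dataclass
class HairpinReport:
    nat_id: str
    mirna_id: str
    mature_locus: tuple[int, int]
    structure: str
    mature_paired: int
    max_bulge: int
    arm: str  # 5p | 3p | none
    pass_: bool
    reason: str = ""


def _validate_mature(mature: str) -> str:
    seq = normalize_seq(mature)
    if not 18 <= len(seq) <= 26:
        raise ValueError(f"mature miRNA must be 18-26 nt, got {len(seq)}")
    if set(seq) - set("ACGT"):
        raise ValueError("mature miRNA contains non-ACGU characters")
    return seq


def _position_penalty(mirna_base: str, target_base: str) -> tuple[float, str]:
    """(penalty, kind) for one miRNA/target position; kind in match|wobble|mismatch."""
    if (mirna_base, target_base) in _WC:
        return 0.0, "match"
    if (mirna_base, target_base) in _WOBBLE:
        return WOBBLE_PENALTY, "wobble"
    return MISMATCH_PENALTY, "mismatch"


def scan_targets(
    mirna: str,
    st: Transcript,
    overlap_regions: Sequence[tuple[int, int]] = (),
    cutoff: float = EXPECTATION_CUTOFF,
    mirna_id: str = "miRNA",
) -> list[MirnaHit]:
    """Scan the ST spliced sequence for miRNA target sites.

    miRNA position 1 is the 5' end of the mature sequence; position i pairs
    with the target-site base i from the 3' end of the site.  Penalties are
    doubled at positions 2-13.  A mismatch (not a wobble) at positions 9-11
    calls translational inhibition; otherwise cleavage.
    """
    m = _validate_mature(mirna)
    L = len(m)
    target = st.spliced_seq
    hits = []
    for off in range(len(target) - L + 1):
        site = target[off : off + L]
        expectation = 0.0
        central_mismatch = False
        for i in range(1, L + 1):
            pen, kind = _position_penalty(m[i - 1], site[L - i])
            if SEED_REGION[0] <= i <= SEED_REGION[1]:
                pen *= 2.0
            expectation += pen
            if kind == "mismatch" and CENTER_REGION[0] <= i <= CENTER_REGION[1]:
                central_mismatch = True
            if expectation > cutoff:
                break
        if expectation > cutoff:
            continue
        site_iv = (off, off + L)
        in_overlap = any(site_iv[0] < e and s < site_iv[1] for s, e in overlap_regions)
        hits.append(
            MirnaHit(
                mirna_id=mirna_id,
                st_id=st.id,
                site_interval=site_iv,
                expectation=expectation,
                inhibition="translation" if central_mismatch else "cleavage",
                in_overlap=in_overlap,
                aligned_mirna=to_rna(m),
                aligned_st=to_rna(site),
            )
        )
    return hits


def find_mirna_origins(
    mirnas: Mapping[str, str],
    nats: Sequence[Transcript],
    overlap_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    max_mismatches: int = 1,
) -> list[dict]:
    """Loci where a mature miRNA matches within a NAT (<= 1 mismatch).

    Both orientations of the mature sequence are tried, normalized to the
    NAT's own 5'->3' axis.  Each locus reports whether it falls inside the
    SAT overlap region.
    """
    from .core_model import revcomp

    overlap_regions = overlap_regions or {}
    out = []
    for nat in nats:
        seq = nat.spliced_seq
        regions = overlap_regions.get(nat.id, ())
        for mid, mature in sorted(mirnas.items()):
            mseq = _validate_mature(mature)
            for orientation, probe in (("sense", mseq), ("antisense", revcomp(mseq))):
                L = len(probe)
                for off in range(len(seq) - L + 1):
                    mm = sum(1 for a, b in zip(probe, seq[off : off + L]) if a != b)
                    if mm <= max_mismatches:
                        iv = (off, off + L)
                        out.append(
                            {
                                "nat_id": nat.id,
                                "mirna_id": mid,
                                "offset": off,
                                "end": off + L,
                                "mismatches": mm,
                                "orientation": orientation,
                                "in_overlap": any(iv[0] < e and s < iv[1] for s, e in regions),
                            }
                        )
    return out


# ---------------------------------------------------------------------------
# Folding

@njit(cache=False)
def _nussinov_fill(codes: np.ndarray, pairable: np.ndarray, minloop: int) -> np.ndarray:
    n = len(codes)
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(minloop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            if pairable[codes[i], codes[j]]:
                inner = M[i + 1, j - 1] if i + 1 <= j - 1 else 0
                if inner + 1 > best:
                    best = inner + 1
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M


def _nussinov_pairs(seq: str, minloop: int = MIN_LOOP) -> list[tuple[int, int]]:
    """Base pairs of one maximum-pairing nested structure.

    Deterministic traceback: pairing (i, j) is preferred over any
    bifurcation on ties; the leftmost split is taken otherwise.
    """
    codes = encode(normalize_seq(seq))
    n = len(codes)
    if n == 0:
        return []
    M = _nussinov_fill(codes, _PAIRABLE, minloop)
    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= minloop:
            continue
        if _PAIRABLE[codes[i], codes[j]]:
            inner = M[i + 1, j - 1] if i + 1 <= j - 1 else 0
            if M[i, j] == inner + 1:
                pairs.append((i, j))
                stack.append((i + 1, j - 1))
                continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if M[i, k] + M[k + 1, j] == M[i, j]:
                stack.append((k + 1, j))
                stack.append((i, k))
                break
    return sorted(pairs)


def fold_region(seq: str) -> str:
    """Dot-bracket structure of one maximum base-pair nested fold."""
    if len(seq) > MAX_FOLD_LEN:
        raise ValueError(f"fold_region accepts at most {MAX_FOLD_LEN} nt, got {len(seq)}")
    pairs = _nussinov_pairs(seq)
    dots = ["."] * len(seq)
    for i, j in pairs:
        dots[i] = "("
        dots[j] = ")"
    return "".join(dots)


def count_pairs(structure: str) -> int:
    return structure.count("(")


# ---------------------------------------------------------------------------
# Precursor evaluation

MAX_UNPAIRED_MATURE = 5
MAX_BULGE = 3
MIN_FLANK_BEYOND_MATURE = 30


def evaluate_precursor(
    nat: Transcript | str,
    mature_locus: tuple[int, int],
    flank: int = DEFAULT_FLANK,
    mirna_id: str = "miRNA",
) -> HairpinReport:
    """Fold mature +/- flank within the NAT and judge the hairpin.

    Pass criteria: the mature lies fully on one arm of the stem-loop (no
    partner inside the mature, all partners on one side), at most 5 mature
    positions are unpaired, and no internal bulge within the mature exceeds
    3 nt.
    """
    seq = nat.spliced_seq if isinstance(nat, Transcript) else normalize_seq(nat)
    nat_id = nat.id if isinstance(nat, Transcript) else "seq"
    start, end = mature_locus
    if not (0 <= start < end <= len(seq)):
        raise ValueError("mature locus outside the NAT")
    w0 = max(0, start - flank)
    w1 = min(len(seq), end + flank)
    mature_len = end - start
    report = HairpinReport(
        nat_id=nat_id,
        mirna_id=mirna_id,
        mature_locus=mature_locus,
        structure="",
        mature_paired=0,
        max_bulge=0,
        arm="none",
        pass_=False,
    )
    if (w1 - w0) < mature_len + MIN_FLANK_BEYOND_MATURE:
        report.reason = "insufficient flank"
        return report
    window = seq[w0:w1]
    pairs = _nussinov_pairs(window)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    m0, m1 = start - w0, end - w0
    mature_idx = range(m0, m1)
    paired = [k for k in mature_idx if k in partner]
    report.mature_paired = len(paired)
    # largest bulge in the mature:star duplex: for consecutive paired mature
    # positions, the unpaired stretch on either strand between them
    max_bulge = 0
    for k1, k2 in zip(paired, paired[1:]):
        gap_m = k2 - k1 - 1
        gap_s = abs(partner[k1] - partner[k2]) - 1
        max_bulge = max(max_bulge, gap_m, gap_s)
    report.max_bulge = max_bulge
    partners = [partner[k] for k in paired]
    dots = ["."] * len(window)
    for i, j in pairs:
        dots[i], dots[j] = "(", ")"
    report.structure = "".join(dots)
    if not partners:
        report.reason = "mature unpaired"
        return report
    inside = [p for p in partners if m0 <= p < m1]
    all_right = all(p >= m1 for p in partners)
    all_left = all(p < m0 for p in partners)
    report.arm = "5p" if all_right else ("3p" if all_left else "none")
    if inside or not (all_right or all_left):
        report.reason = "mature not confined to one arm"
        return report
    # the mature must sit on the arm of a genuine stem-loop: the region
    # enclosed by the innermost mature pair (toward the loop) may continue
    # the stem or hold a terminal loop, but must not branch into multiple
    # helices (a multiloop is not a hairpin arm)
    if all_right:
        k_in = max(paired)
        lo, hi = k_in, partner[k_in]
    else:
        k_in = min(paired)
        lo, hi = partner[k_in], k_in
    enclosed = [(i, j) for i, j in pairs if lo < i and j < hi]
    enclosed.sort()
    for (a1, b1), (a2, b2) in zip(enclosed, enclosed[1:]):
        if a2 > b1:  # two disjoint helices inside the loop -> multibranch
            report.reason = "multibranch loop"
            return report
    if (mature_len - report.mature_paired) > MAX_UNPAIRED_MATURE:
        report.reason = f"more than {MAX_UNPAIRED_MATURE} unpaired mature positions"
        return report
    if report.max_bulge > MAX_BULGE:
        report.reason = f"bulge longer than {MAX_BULGE} nt"
        return report
    report.pass_ = True
    return report
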