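"""Classification and summary statistics for discovered SAT pairs.

cis-NAT positional types follow the span geometry: convergent (3'-ends
overlapping), divergent (5'-ends overlapping), S>N (ST contains the NAT)
and N>S (NAT contains the ST).  Containment is checked on genomic spans and
takes precedence over the end-overlap calls; identical spans resolve to S>N
with a logged note.  Relationship multiplexing (1v1 / 1vn / nv1 / nvn) is
read off the bipartite NAT-ST degree structure.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import alignment
from .core_model import Transcript
from .nat_discovery import SATPair

logger = logging.getLogger(__name__)

POSITIONAL_TYPES = ("divergent", "convergent", "S>N", "N>S")
RELATIONSHIPS = ("1v1", "1vn", "nv1", "nvn")

CONSERVATION_WORD_SIZE = 7
CONSERVATION_MIN_SCORE = 50
CONSERVATION_COVERAGE = 0.5


@dataclass
class PairStats:
    overlap_total: int
    frac_of_st: float
    frac_of_nat: float
    positional_type: str | None
    relationship: str | None


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage of ``part`` in ``whole``, rounded as printed in reports."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round(100.0 * part / whole, ndigits)


def classify_cis_type(st: Transcript, nat: Transcript) -> str:
    """Positional type of a cis pair from its genomic span geometry."""
    if st.strand == nat.strand:
        raise ValueError("cis pair must lie on opposite strands")
    ss, se = st.span
    ns, ne = nat.span
    if se <= ns or ne <= ss:
        raise ValueError(f"spans of {st.id} and {nat.id} do not overlap")
    if (ss, se) == (ns, ne):
        logger.info("identical spans for %s/%s: tie resolved to S>N", st.id, nat.id)
        return "S>N"
    if ns <= ss and se <= ne:
        return "N>S"
    if ss <= ns and ne <= se:
        return "S>N"
    ov_s, ov_e = max(ss, ns), min(se, ne)

    def inside(p: int) -> bool:
        return ov_s <= p < ov_e

    if inside(st.three_prime()) and inside(nat.three_prime()):
        return "convergent"
    if inside(st.five_prime()) and inside(nat.five_prime()):
        return "divergent"
    raise ValueError(f"unclassifiable geometry for {st.id}/{nat.id}")  # pragma: no cover


def classify_relationships(pairs: Sequence[SATPair]) -> dict[tuple[str, str], str]:
    """Relationship label per pair from NAT and ST degrees.

    d_N = number of STs the pair's NAT maps to; d_S = number of NATs mapping
    to the pair's ST.  1v1: both 1; 1vn: d_N>1 (one NAT, many STs);
    nv1: d_S>1; nvn: both >1.  Labels are also written onto the pairs.
    """
    edges = {(p.st_id, p.nat_id) for p in pairs}
    d_nat = Counter(nat for _, nat in edges)
    d_st = Counter(st for st, _ in edges)
    labels = {}
    for p in pairs:
        dn, ds = d_nat[p.nat_id], d_st[p.st_id]
        if dn == 1 and ds == 1:
            lab = "1v1"
        elif dn > 1 and ds == 1:
            lab = "1vn"
        elif dn == 1 and ds > 1:
            lab = "nv1"
        else:
            lab = "nvn"
        labels[(p.st_id, p.nat_id)] = lab
        p.relationship = lab
    return labels


def annotate_positional_types(
    pairs: Sequence[SATPair], transcripts: Mapping[str, Transcript]
) -> None:
    for p in pairs:
        if p.category == "cis":
            p.positional_type = classify_cis_type(transcripts[p.st_id], transcripts[p.nat_id])


def pair_stats(pair: SATPair) -> PairStats:
    total = pair.total_overlap
    return PairStats(
        overlap_total=total,
        frac_of_st=total / pair.st_len,
        frac_of_nat=total / pair.nat_len,
        positional_type=pair.positional_type,
        relationship=pair.relationship,
    )


def _length_histogram(lengths: Sequence[int], bin_width: int = 100, origin: int = 200) -> dict[str, int]:
    hist: dict[str, int] = {}
    for n in lengths:
        lo = origin + bin_width * max(0, (n - origin) // bin_width)
        hist_key = f"{lo}-{lo + bin_width}"
        hist[hist_key] = hist.get(hist_key, 0) + 1
    return dict(sorted(hist.items(), key=lambda kv: int(kv[0].split("-")[0])))


def summarize(
    pairs: Sequence[SATPair], transcripts: Mapping[str, Transcript]
) -> dict[str, dict]:
    """Per-category NAT length/exon statistics, overlap fractions and
    positional/relationship counts."""
    classify_relationships(pairs)
    annotate_positional_types(pairs, transcripts)
    out: dict[str, dict] = {}
    for category in ("cis", "trans"):
        cat_pairs = [p for p in pairs if p.category == category]
        nat_ids = sorted({p.nat_id for p in cat_pairs})
        lengths = [transcripts[i].length for i in nat_ids]
        exons = [transcripts[i].n_exons for i in nat_ids]
        stats = [pair_stats(p) for p in cat_pairs]
        entry = {
            "n_pairs": len(cat_pairs),
            "n_nats": len(nat_ids),
            "nat_length_min": int(min(lengths)) if lengths else None,
            "nat_length_max": int(max(lengths)) if lengths else None,
            "nat_length_mean": round(float(np.mean(lengths)), 2) if lengths else None,
            "nat_exons_mean": round(float(np.mean(exons)), 2) if exons else None,
            "length_histogram": _length_histogram(lengths),
            "mean_frac_of_st": round(float(np.mean([s.frac_of_st for s in stats])), 4)
            if stats
            else None,
            "mean_frac_of_nat": round(float(np.mean([s.frac_of_nat for s in stats])), 4)
            if stats
            else None,
            "relationship_counts": dict(
                Counter(p.relationship for p in cat_pairs)
            ),
        }
        if category == "cis":
            entry["positional_type_counts"] = dict(Counter(p.positional_type for p in cat_pairs))
        out[category] = entry
    return out


def conservation_scan(
    nats: Mapping[str, str],
    reference_lncrnas: Mapping[str, str],
    word_size: int = CONSERVATION_WORD_SIZE,
    min_score: float = CONSERVATION_MIN_SCORE,
    coverage: float = CONSERVATION_COVERAGE,
) -> pd.DataFrame:
    """Same-strand homology scan of NATs against a user-provided lncRNA set.

    A hit is kept only when the aligned span covers at least ``coverage`` of
    BOTH sequences.  Coordinates in the report are 1-based inclusive.
    """
    rows = []
    for nat_id, nat_seq in nats.items():
        for ref_id, ref_seq in reference_lncrnas.items():
            hits = alignment.seeded_local_align(
                nat_seq, ref_seq, word_size=word_size, min_score=min_score, max_hits=1
            )
            for h in hits:
                if (h.q_end - h.q_start) < coverage * len(nat_seq):
                    continue
                if (h.s_end - h.s_start) < coverage * len(ref_seq):
                    continue
                rows.append(
                    {
                        "nat_id": nat_id,
                        "subject_id": ref_id,
                        "identity": round(100.0 * h.identity, 2),
                        "alignment_length": h.length,
                        "q_start": h.q_start + 1,
                        "q_end": h.q_end,
                        "s_start": h.s_start + 1,
                        "s_end": h.s_end,
                    }
                )
    cols = [
        "nat_id",
        "subject_id",
        "identity",
        "alignment_length",
        "q_start",
        "q_end",
        "s_start",
        "s_end",
    ]
    return pd.DataFrame(rows, columns=cols)
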