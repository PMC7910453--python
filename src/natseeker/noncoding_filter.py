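"""Noncoding filter cascade for candidate NATs.

A candidate NAT is retained only if it is at least 200 nt long, carries no
open reading frame of 100 aa or more on its own strand, matches no protein
database (external evidence hook) and has no positive coding-potential
score (external evidence hook).  The ORF scan mirrors `getorf -minsize 300
-find 1 -reverse N` semantics: ATG-initiated, stop-terminated frames on the
given strand only; the filter tests the start-through-stop span (stop codon
included), while the coding-region length excluding the stop is also
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_model import STOP_CODONS, Transcript, normalize_seq
from .nat_discovery import SATPair

logger = logging.getLogger(__name__)

MIN_NAT_LEN = 200
MAX_ORF_SPAN = 300  # nt, 100 aa equivalence


@dataclass
class OrfScan:
    """Longest ORF on the forward strand of a sequence."""

    max_orf_nt: int   # coding region, stop codon excluded
    max_span_nt: int  # start-through-stop span, stop codon included


@dataclass
class CodingEvidence:
    transcript_id: str
    max_orf_nt: int = 0
    max_span_nt: int = 0
    protein_hit: bool = False
    cpc_score: float | None = None
    verdict: str = "noncoding"  # noncoding | coding | undetermined
    reasons: list[str] = field(default_factory=list)


def length_filter(transcript: Transcript, min_len: int = MIN_NAT_LEN) -> bool:
    """True iff the spliced length reaches the minimum (200 nt by default);
    shorter transcripts are removed."""
    return transcript.length >= min_len


def find_max_orf(seq: str) -> OrfScan:
    """Longest ATG..stop open reading frame over the three forward frames.

    Unterminated ORFs (no stop before the sequence end) are not counted,
    matching getorf's start-to-stop mode.
    """
    seq = normalize_seq(seq)
    best_cds = 0
    for frame in range(3):
        open_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    best_cds = max(best_cds, i - open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return OrfScan(max_orf_nt=best_cds, max_span_nt=best_cds + 3 if best_cds else 0)


def read_hooks(path) -> dict[str, dict]:
    """Load an external-evidence TSV: transcript_id, protein_hit, cpc_score."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    out = {}
    for _, row in df.iterrows():
        cpc = row.get("cpc_score")
        out[row["transcript_id"]] = {
            "protein_hit": bool(row.get("protein_hit", False)),
            "cpc_score": None if pd.isna(cpc) else float(cpc),
        }
    return out


def evaluate_nat(
    nat: Transcript,
    hooks: Mapping[str, Mapping] | None = None,
    min_len: int = MIN_NAT_LEN,
    max_orf_span: int = MAX_ORF_SPAN,
) -> CodingEvidence:
    """Score one candidate NAT against the full filter cascade."""
    scan = find_max_orf(nat.spliced_seq)
    hook = (hooks or {}).get(nat.id, {})
    protein_hit = bool(hook.get("protein_hit", False))
    cpc = hook.get("cpc_score")
    ev = CodingEvidence(
        transcript_id=nat.id,
        max_orf_nt=scan.max_orf_nt,
        max_span_nt=scan.max_span_nt,
        protein_hit=protein_hit,
        cpc_score=cpc,
    )
    if scan.max_span_nt >= max_orf_span:
        ev.reasons.append(f"orf>={max_orf_span}")
    if protein_hit:
        ev.reasons.append("protein_hit")
    if cpc is not None and cpc > 0:
        ev.reasons.append("cpc>0")
    coding = bool(ev.reasons)
    if not length_filter(nat, min_len):
        ev.reasons.append(f"len<{min_len}")
    ev.verdict = "coding" if coding else ("noncoding" if not ev.reasons else "undetermined")
    return ev


def apply_filters(
    candidates: Sequence[SATPair],
    transcripts: Mapping[str, Transcript],
    hooks: Mapping[str, Mapping] | None = None,
    min_len: int = MIN_NAT_LEN,
    max_orf_span: int = MAX_ORF_SPAN,
) -> tuple[list[SATPair], dict[str, CodingEvidence]]:
    """Drop pairs whose NAT fails any rule; return kept pairs and evidence.

    The three coding rules and the length rule are independent, so the kept
    set does not depend on the order they are applied in.
    """
    if hooks:
        nat_ids = {p.nat_id for p in candidates}
        unknown = sorted(set(hooks) - nat_ids)
        if unknown:
            logger.warning("evidence hooks reference %d unknown transcripts", len(unknown))
    evidence: dict[str, CodingEvidence] = {}
    kept = []
    for pair in candidates:
        if pair.nat_id not in evidence:
            evidence[pair.nat_id] = evaluate_nat(
                transcripts[pair.nat_id], hooks, min_len=min_len, max_orf_span=max_orf_span
            )
        if not evidence[pair.nat_id].reasons:
            kept.append(pair)
    return kept, evidence


def evidence_table(evidence: Mapping[str, CodingEvidence]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": ev.transcript_id,
            "max_orf_nt": ev.max_orf_nt,
            "max_span_nt": ev.max_span_nt,
            "protein_hit": ev.protein_hit,
            "cpc_score": ev.cpc_score,
            "verdict": ev.verdict,
            "reasons": ";".join(ev.reasons),
        }
        for ev in evidence.values()
    ]
    return pd.DataFrame(rows).sort_values("transcript_id").reset_index(drop=True)
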