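"""Seeded generators of genomes, annotations, expression matrices and miRNA
fixtures with planted ground truth for every pipeline stage.

Design notes
------------
* Sequence destined to become a noncoding NAT is generated "stop-rich": a
  ``TAAATAAATAA`` block (one stop codon in each reading frame) is inserted
  at most every 70 nt, so no ATG-to-stop span on the NAT strand can reach
  the 300-nt coding filter.  Wherever other content is written over a NAT
  (a planted ORF on the opposite strand, a hairpin insert, identity
  mutations), a verify-and-repair loop re-draws the random content until
  the NAT is ORF-clean again.
* Expression is generated on the log2 scale as a bivariate normal per pair
  (tissue effects plus replicate noise, both sharing one latent
  correlation), then exponentiated to FPKM.  The latent correlation is
  corrected for the lognormal transform so that the *expected Pearson r of
  the FPKM values* equals the requested target.
* All randomness flows through explicit integer seeds; there is no global
  RNG state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    ExpressionMatrix,
    GenomeStore,
    Transcript,
    revcomp,
    normalize_seq,
)
from .noncoding_filter import find_max_orf
from .mirna_analysis import evaluate_precursor, _validate_mature

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
STOP_BLOCK = "TAAATAAATAA"  # a stop codon in each of the three frames
ORF_SPAN = 402  # planted coding ORF: ATG + 132 codons + TAA (134 codons)
DEFAULT_BETWEEN_SD = 0.8  # log2 tissue-effect SD (~4-fold swings between tissues)
DEFAULT_NOISE_SD = 0.4    # log2 replicate-noise SD (~30% replicate CV)
FPKM_FLOOR = 4.0          # min max-tissue-mean FPKM enforced per transcript

# canonical plant miR156a mature sequence pattern (20 nt)
MIR156A = "UGACAGAAGAGAGUGAGCAC"
MIR_NOVEL = "UUGGACUGAAGGGAGCUCCCU"[:21]  # invented 21-nt mature for the second plant


# ---------------------------------------------------------------------------
# Sequence helpers

def rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def stopful_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random sequence guaranteed to contain no forward ORF span >= 300 nt."""
    parts, pos = [], 0
    while pos < n:
        c = min(70, n - pos)
        parts.append(rand_seq(rng, c, gc))
        pos += c
        if pos < n:
            b = STOP_BLOCK[: min(len(STOP_BLOCK), n - pos)]
            parts.append(b)
            pos += len(b)
    return "".join(parts)


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


def orf_seq(rng: np.random.Generator, n_codons: int = ORF_SPAN // 3) -> str:
    """ATG-initiated, TAA-terminated ORF of span 3 * n_codons nt."""
    body = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _write(genome: GenomeStore, chrom: str, pos: int, seq: str) -> None:
    s = genome.contigs[chrom]
    if pos < 0 or pos + len(seq) > len(s):
        raise ValueError(f"write outside contig {chrom!r}")
    genome.contigs[chrom] = s[:pos] + seq + s[pos + len(seq) :]


def _write_nat_spliced(genome: GenomeStore, nat: Transcript, spliced: str) -> None:
    """Write a full spliced sequence for ``nat`` back into the genome."""
    if len(spliced) != nat.length:
        raise ValueError("spliced sequence length mismatch")
    genomic = revcomp(spliced) if nat.strand == "-" else spliced
    off = 0
    for a, b in nat.exons:
        _write(genome, nat.chrom, a, genomic[off : off + (b - a)])
        off += b - a


# ---------------------------------------------------------------------------
# Truth bookkeeping

@dataclass
class PlantedTruth:
    cis_pairs: list[dict] = field(default_factory=list)
    trans_pairs: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    correlation_targets: dict[str, float] = field(default_factory=dict)
    mirna_plants: list[dict] = field(default_factory=list)

    @property
    def pair_keys(self) -> set[tuple[str, str]]:
        return {
            (rec["st_id"], rec["nat_id"]) for rec in self.cis_pairs + self.trans_pairs
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# Genome

def generate_genome(
    n_contigs: int, contig_len: int, gc: float = 0.5, seed: int = 0
) -> GenomeStore:
    """Random contigs named chr01, chr02, ... with the requested GC content."""
    if contig_len < 5000:
        raise ValueError("contig_len must be >= 5000")
    rng = np.random.default_rng(seed)
    contigs = {
        f"chr{i + 1:02d}": rand_seq(rng, contig_len, gc) for i in range(n_contigs)
    }
    return GenomeStore(contigs)


# ---------------------------------------------------------------------------
# cis pairs

def plant_cis_pair(
    genome: GenomeStore,
    chrom: str,
    positional_type: str,
    overlap_len: int,
    st_id: str,
    nat_id: str,
    seed: int,
    anchor: int = 100,
    exon_plan: Mapping | None = None,
    st_extra: int = 450,
    nat_extra: int = 200,
) -> tuple[Transcript, Transcript, dict]:
    """Plant an overlapping (cis) SAT pair of the requested positional type.

    The ST sits on +, the NAT on -.  The ST carries a planted ORF of span
    402 nt wherever the geometry leaves room for one outside the overlap;
    the NAT is built ORF-free.  Truth records the exact genomic overlap
    regions.
    """
    if overlap_len < 1:
        raise ValueError("overlap_len must be >= 1")
    rng = np.random.default_rng(seed)
    a = anchor
    orf_pos: int | None = None

    if exon_plan is not None:
        segments = list(exon_plan["segments"])
        gaps = list(exon_plan.get("gaps") or [60] * (len(segments) - 1))
        if len(gaps) != len(segments) - 1:
            raise ValueError("exon_plan needs one gap fewer than segments")
        window = sum(segments) + sum(gaps)
        m_left, m_right = 420, 80
        st_exons = [(a, a + m_left + window + m_right)]
        nat_exons = []
        pos = a + m_left
        for k, seg in enumerate(segments):
            nat_exons.append((pos, pos + seg))
            pos += seg + (gaps[k] if k < len(gaps) else 0)
        overlap_ivs = list(nat_exons)
        orf_pos = a + 10
        positional_type = "S>N"
    elif positional_type == "convergent":
        ls = overlap_len + st_extra
        ln = overlap_len + nat_extra
        st_exons = [(a, a + ls)]
        nat_exons = [(a + ls - overlap_len, a + ls - overlap_len + ln)]
        overlap_ivs = [(a + ls - overlap_len, a + ls)]
        orf_pos = a + 10
    elif positional_type == "divergent":
        ln = overlap_len + nat_extra
        ls = overlap_len + st_extra
        nat_exons = [(a, a + ln)]
        st_exons = [(a + ln - overlap_len, a + ln - overlap_len + ls)]
        overlap_ivs = [(a + ln - overlap_len, a + ln)]
        orf_pos = a + ln + 10
    elif positional_type == "S>N":
        m_left, m_right = 420, 80
        st_exons = [(a, a + m_left + overlap_len + m_right)]
        nat_exons = [(a + m_left, a + m_left + overlap_len)]
        overlap_ivs = list(nat_exons)
        orf_pos = a + 10
    elif positional_type == "N>S":
        margin = 120
        ln = overlap_len + 2 * margin
        nat_exons = [(a, a + ln)]
        st_exons = [(a + margin, a + margin + overlap_len)]
        overlap_ivs = list(st_exons)
        orf_pos = None  # ORF lives inside the NAT span; handled below
    else:
        raise ValueError(f"unknown positional type {positional_type!r}")

    if st_exons[-1][1] > genome.length(chrom) or nat_exons[-1][1] > genome.length(chrom):
        raise ValueError("infeasible geometry: pair does not fit in the contig")

    st = Transcript(id=st_id, chrom=chrom, strand="+", exons=st_exons, biotype="coding")
    nat = Transcript(id=nat_id, chrom=chrom, strand="-", exons=nat_exons, biotype="unknown")

    # NAT content first (stop-rich on the NAT strand), then the ST ORF.
    _write_nat_spliced(genome, nat, stopful_seq(rng, nat.length))
    if positional_type == "N>S":
        # The whole ST lies inside the NAT; plant the ORF only if it fits,
        # and re-draw its codons until the NAT strand stays ORF-free.
        if st.length >= ORF_SPAN + 12:
            for _attempt in range(200):
                st_seq = (
                    rand_seq(rng, 6)
                    + orf_seq(rng)
                    + stopful_seq(rng, st.length - ORF_SPAN - 6)
                )
                _write(genome, chrom, st.start, st_seq)
                nat.extract(genome)
                if find_max_orf(nat.spliced_seq).max_span_nt < 300:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not sanitize N>S pair")
    elif orf_pos is not None:
        _write(genome, chrom, orf_pos, orf_seq(rng))

    st.extract(genome)
    nat.extract(genome)
    assert find_max_orf(nat.spliced_seq).max_span_nt < 300
    truth = {
        "st_id": st_id,
        "nat_id": nat_id,
        "positional_type": positional_type,
        "relationship": "1v1",
        "overlap_regions": [[int(s), int(e)] for s, e in overlap_ivs],
        "overlap_lengths": [int(e - s) for s, e in overlap_ivs],
    }
    return st, nat, truth


# ---------------------------------------------------------------------------
# trans pairs

def _bubble_positions(n: int, bubbles: Sequence[tuple[int, int]]) -> set[int]:
    pos: set[int] = set()
    for off, blen in bubbles:
        if off < 0 or off + blen > n:
            raise ValueError("bubble exceeds the complementary region")
        pos.update(range(off, off + blen))
    return pos


def _mutate_region(
    rng: np.random.Generator, region: str, identity: float, bubbles: Sequence[tuple[int, int]]
) -> tuple[str, float]:
    """Apply point mutations and bubble replacements to a perfect region.

    Point mutations replace a base with its complement (equal to the facing
    partner base), which pairs with the partner neither Watson-Crick nor
    wobble.  Bubble stretches become ``C`` runs facing planted ``T`` runs
    (see plant_trans_pair), unpairable both in register and off-register,
    so the planted bubble survives the base-pair-maximization check intact.
    """
    chars = list(region)
    n = len(chars)
    bubble_pos = _bubble_positions(n, bubbles)
    mut = rng.random(n) < (1.0 - identity)
    comp = str.maketrans("ACGT", "TGCA")
    n_changed = 0
    for k in range(n):
        if k in bubble_pos:
            chars[k] = "C"
        elif mut[k] and identity < 1.0:
            new = chars[k].translate(comp)
            if new != chars[k]:
                n_changed += 1
                chars[k] = new
    realized = 1.0 - n_changed / n if n else 1.0
    return "".join(chars), realized


def _ensure_seed_word(perfect: str, mutated: str, word: int = 11) -> str:
    """Guarantee a mutation-free exact run of >= ``word`` nt for seeding."""
    run = 0
    for a, b in zip(perfect, mutated):
        run = run + 1 if a == b else 0
        if run >= word:
            return mutated
    return perfect[: word + 4] + mutated[word + 4 :]


def plant_trans_pair(
    genome: GenomeStore,
    chrom: str,
    comp_len: int,
    identity: float,
    bubbles: Sequence[tuple[int, int]],
    st_id: str,
    nat_id: str,
    seed: int,
    st_anchor: int = 100,
    nat_anchor: int = 2500,
) -> tuple[Transcript, Transcript, dict]:
    """Plant a trans SAT pair: the NAT carries the reverse complement of the
    ST's 3'-terminal ``comp_len`` nt, degraded to the requested identity and
    carrying the requested non-complementary bubbles.

    ST and NAT occupy disjoint loci on the same contig.
    """
    if sum(b for _, b in bubbles) >= comp_len:
        raise ValueError("bubbles exceed the complementary region")
    rng = np.random.default_rng(seed)
    nat_flank = 60
    region_nat = list(stopful_seq(rng, comp_len))  # complementary region, NAT orientation
    for k in _bubble_positions(comp_len, bubbles):
        region_nat[k] = "A"  # ST side gets T; NAT side becomes C (unpairable)
    region_nat = "".join(region_nat)
    st_seq = rand_seq(rng, 10) + orf_seq(rng) + rand_seq(rng, 8) + revcomp(region_nat)
    ls = len(st_seq)
    st = Transcript(
        id=st_id, chrom=chrom, strand="+",
        exons=[(st_anchor, st_anchor + ls)], biotype="coding",
    )
    if st.end > nat_anchor:
        raise ValueError("loci overlap: increase nat_anchor")
    _write(genome, chrom, st_anchor, st_seq)
    st.extract(genome)

    ln = nat_flank + comp_len + nat_flank
    nat = Transcript(
        id=nat_id, chrom=chrom, strand="+",
        exons=[(nat_anchor, nat_anchor + ln)], biotype="unknown",
    )
    for _attempt in range(100):
        mutated, realized = _mutate_region(rng, region_nat, identity, bubbles)
        mutated = _ensure_seed_word(region_nat, mutated)
        nat_seq = stopful_seq(rng, nat_flank) + mutated + stopful_seq(rng, nat_flank)
        _write(genome, chrom, nat_anchor, nat_seq)
        nat.extract(genome)
        if find_max_orf(nat.spliced_seq).max_span_nt < 300:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not sanitize trans NAT")
    truth = {
        "st_id": st_id,
        "nat_id": nat_id,
        "comp_len": int(comp_len),
        "identity": float(realized),
        "bubbles": [[int(o), int(b)] for o, b in bubbles],
        "relationship": "1v1",
        "st_region": [ls - comp_len, ls],
        "nat_region": [nat_flank, nat_flank + comp_len],
    }
    return st, nat, truth


# ---------------------------------------------------------------------------
# decoys

def plant_decoy(
    genome: GenomeStore,
    chrom: str,
    reason: str,
    st_id: str,
    nat_id: str,
    seed: int,
) -> tuple[Transcript, Transcript, dict]:
    """Plant a decoy pair violating exactly one retention rule.

    coding_orf: a cis pair whose NAT carries an ORF of span 402 nt.
    short: a cis pair whose NAT is 150 nt (< 200).
    weak_complement: a trans couple whose complementary region is 80 nt.
    """
    rng = np.random.default_rng(seed)
    if reason == "coding_orf":
        st, nat, _ = plant_cis_pair(
            genome, chrom, "convergent", 150, st_id, nat_id,
            seed=int(rng.integers(2**31)), nat_extra=450,
        )
        spliced = list(nat.spliced_seq)
        orf = orf_seq(rng)
        spliced[20 : 20 + len(orf)] = orf  # NAT-only part: spliced [0, 450)
        _write_nat_spliced(genome, nat, "".join(spliced))
        nat.extract(genome)
        st.extract(genome)
        assert find_max_orf(nat.spliced_seq).max_span_nt >= 300
    elif reason == "short":
        st, nat, _ = plant_cis_pair(
            genome, chrom, "convergent", 100, st_id, nat_id,
            seed=int(rng.integers(2**31)), nat_extra=50,
        )
        assert nat.length == 150
    elif reason == "weak_complement":
        st, nat, _ = plant_trans_pair(
            genome, chrom, 80, 1.0, [], st_id, nat_id, seed=int(rng.integers(2**31))
        )
    else:
        raise ValueError(f"unknown decoy reason {reason!r}")
    return st, nat, {"st_id": st_id, "nat_id": nat_id, "reason": reason}


# ---------------------------------------------------------------------------
# Expression

def _latent_rho(target_r: float, sigma2_log2: float) -> float:
    """Latent normal correlation whose lognormal image has Pearson ``target_r``."""
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    s2 = sigma2_log2 * (np.log(2.0) ** 2)
    if s2 == 0 or target_r == 0:
        return float(target_r)
    arg = 1.0 + target_r * (np.exp(s2) - 1.0)
    if arg <= 0:
        logger.warning("target_r %.2f not attainable at this variance; clamping", target_r)
        return -1.0
    rho = np.log(arg) / s2
    return float(np.clip(rho, -1.0, 1.0))


def generate_expression(
    pair_targets: Sequence[tuple[str, str, float]],
    singles: Sequence[str] = (),
    tissues: Sequence[str] = ("f", "l", "r"),
    replicates: int = 3,
    between_sd: float = DEFAULT_BETWEEN_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    tissue_log2_offsets: Mapping[str, Mapping[str, float]] | None = None,
) -> ExpressionMatrix:
    """Tissue-replicate FPKM matrix with planted pairwise correlations.

    Per pair, tissue effects and replicate noise are drawn from bivariate
    normals on the log2 scale sharing one latent correlation, chosen so the
    expected Pearson r of the exponentiated values equals ``target_r``.
    ``tissue_log2_offsets`` plants deterministic tissue fold-changes
    (e.g. a root-specific transcript) on top.
    """
    rng = np.random.default_rng(seed)
    offsets = tissue_log2_offsets or {}
    samples = [f"p{r + 1:02d}_{t}" for t in tissues for r in range(replicates)]
    sample_tissue = [t for t in tissues for _ in range(replicates)]
    sigma2 = between_sd**2 + noise_sd**2
    data: dict[str, np.ndarray] = {}

    def bvn(rho: float, sd: float, size: int) -> tuple[np.ndarray, np.ndarray]:
        z1 = rng.normal(0, 1, size)
        z2 = rng.normal(0, 1, size)
        x = z1
        y = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2
        return x * sd, y * sd

    for st_id, nat_id, target_r in pair_targets:
        rho = _latent_rho(target_r, sigma2)
        base_a, base_b = rng.uniform(2.0, 6.0, size=2)
        u, v = bvn(rho, between_sd, len(tissues))
        e, f = bvn(rho, noise_sd, len(tissues) * replicates)
        xs = np.empty(len(samples))
        ys = np.empty(len(samples))
        for idx, tissue in enumerate(sample_tissue):
            ti = list(tissues).index(tissue)
            xs[idx] = base_a + u[ti] + e[idx]
            ys[idx] = base_b + v[ti] + f[idx]
            xs[idx] += offsets.get(st_id, {}).get(tissue, 0.0)
            ys[idx] += offsets.get(nat_id, {}).get(tissue, 0.0)
        data[st_id] = 2.0**xs
        data[nat_id] = 2.0**ys

    for tid in singles:
        base = rng.uniform(2.0, 6.0)
        u = rng.normal(0, between_sd, len(tissues))
        x = np.array(
            [
                base
                + u[list(tissues).index(t)]
                + rng.normal(0, noise_sd)
                + offsets.get(tid, {}).get(t, 0.0)
                for t in sample_tissue
            ]
        )
        data[tid] = 2.0**x

    df = pd.DataFrame(data, index=samples).T
    df.columns = samples
    # enforce the expression floor: every transcript detectable in >= 1 tissue
    # (a pure rescaling, which leaves Pearson correlations unchanged)
    for tid in df.index:
        row = df.loc[tid]
        tissue_means = [row[[s for s, t in zip(samples, sample_tissue) if t == tt]].mean()
                        for tt in tissues]
        m = max(tissue_means)
        if m < FPKM_FLOOR:
            df.loc[tid] = row * (FPKM_FLOOR / m)
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# miRNA hairpin plants

def plant_mirna_hairpin(
    genome: GenomeStore,
    nat: Transcript,
    mature: str,
    mirna_id: str,
    insert_offset: int,
    seed: int,
    star_mismatches: int = 0,
    ext: int = 35,
    loop: int = 18,
) -> dict:
    """Insert a pre-miRNA stem-loop into a NAT (overwriting in place).

    Layout on the NAT 5'->3' axis: extension arm, mature, loop, miRNA*
    (revcomp of the mature with <= 2 mismatches), revcomp of the extension
    arm.  The mature therefore sits on the 5p arm.  The insert is re-drawn
    until the planted precursor passes the hairpin criteria and the NAT
    remains ORF-free.
    """
    mseq = _validate_mature(mature)
    if star_mismatches > 2:
        raise ValueError("miRNA* may carry at most 2 mismatches")
    if loop < 15:
        raise ValueError("loop must be >= 15 nt")
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGT", "TGCA")
    insert_len = 2 * ext + 2 * len(mseq) + loop
    if insert_offset < 0 or insert_offset + insert_len > nat.length:
        raise ValueError("hairpin insert does not fit in the NAT")
    mature_off = insert_offset + ext
    for _attempt in range(100):
        ext5 = rand_seq(rng, ext)
        loop_seq = rand_seq(rng, loop)
        star = list(revcomp(mseq))
        if star_mismatches:
            pos = rng.choice(np.arange(3, len(star) - 3), size=star_mismatches, replace=False)
            for p in pos:
                star[p] = star[p].translate(comp)
        insert = ext5 + mseq + loop_seq + "".join(star) + revcomp(ext5)
        spliced = list(nat.spliced_seq)
        spliced[insert_offset : insert_offset + insert_len] = insert
        candidate = "".join(spliced)
        if find_max_orf(candidate).max_span_nt >= 300:
            continue
        report = evaluate_precursor(candidate, (mature_off, mature_off + len(mseq)))
        if not report.pass_:
            continue
        _write_nat_spliced(genome, nat, candidate)
        nat.extract(genome)
        return {
            "nat_id": nat.id,
            "mirna_id": mirna_id,
            "mature": mature if "U" in mature.upper() else mseq,
            "arm": "5p",
            "offset": int(mature_off),
            "length": len(mseq),
            "star_mismatches": int(star_mismatches),
        }
    raise RuntimeError("could not plant a passing hairpin")  # pragma: no cover


# ---------------------------------------------------------------------------
# Full fixture

@dataclass
class Fixture:
    genome: GenomeStore
    transcripts: list[Transcript]
    coding_ids: list[str]
    expression: ExpressionMatrix
    truth: PlantedTruth
    mirnas: dict[str, str]

    @property
    def by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}


CIS_PLAN = [
    # (positional type, overlap length); three per type
    ("divergent", 150), ("divergent", 220), ("divergent", 260),
    ("convergent", 101), ("convergent", 150), ("convergent", 330),
    ("S>N", 330), ("S>N", 300), ("S>N", None),  # None -> four-segment exon plan
    ("N>S", 450), ("N>S", 460), ("N>S", 500),
]
FOUR_SEGMENT_PLAN = {"segments": [181, 38, 165, 49], "gaps": [60, 60, 60]}
TRANS_COMP_LENS = [150, 180, 200, 220, 250, 270, 300, 320, 340, 360, 380, 400]
TRANS_IDENTITY = [1.0, 1.0, 0.98, 0.98, 0.97, 0.97, 0.96, 0.96, 0.95, 0.95, 1.0, 0.98]
DECOY_PLAN = ["coding_orf"] * 7 + ["short"] * 7 + ["weak_complement"] * 6
CIS_TARGET_R = [0.99, 0.5, 0.0] * 4
TRANS_TARGET_R = [0.99, 0.99, 0.5, 0.0, -0.6, 0.0] * 2


def default_fixture(seed: int = 42) -> Fixture:
    """The study-condition fixture: 12 cis pairs (3 per positional type),
    12 trans pairs (complementary regions 150-400 nt at identity >= 0.95),
    20 decoys, tissue-replicate expression with planted correlations, and
    two planted miRNA hairpins (one inside an overlap region, one outside)."""
    master = np.random.default_rng(seed)
    n_units = len(CIS_PLAN) + len(TRANS_COMP_LENS) + len(DECOY_PLAN)
    genome = generate_genome(n_units, 6000, gc=0.5, seed=int(master.integers(2**31)))
    contigs = iter(sorted(genome.contigs))
    truth = PlantedTruth()
    transcripts: list[Transcript] = []
    unit_seed = lambda: int(master.integers(2**31))  # noqa: E731

    cis_nats: list[Transcript] = []
    for k, (ptype, ov) in enumerate(CIS_PLAN):
        chrom = next(contigs)
        if ov is None:
            st, nat, rec = plant_cis_pair(
                genome, chrom, ptype, 1, f"ST{k + 1:04d}", f"NAT{k + 1:04d}",
                seed=unit_seed(), exon_plan=FOUR_SEGMENT_PLAN,
            )
        else:
            st, nat, rec = plant_cis_pair(
                genome, chrom, ptype, ov, f"ST{k + 1:04d}", f"NAT{k + 1:04d}", seed=unit_seed()
            )
        transcripts += [st, nat]
        cis_nats.append(nat)
        truth.cis_pairs.append(rec)

    for k, (cl, ident) in enumerate(zip(TRANS_COMP_LENS, TRANS_IDENTITY)):
        chrom = next(contigs)
        idx = len(CIS_PLAN) + k + 1
        st, nat, rec = plant_trans_pair(
            genome, chrom, cl, ident, [], f"ST{idx:04d}", f"NAT{idx:04d}", seed=unit_seed()
        )
        transcripts += [st, nat]
        truth.trans_pairs.append(rec)

    for k, reason in enumerate(DECOY_PLAN):
        chrom = next(contigs)
        idx = len(CIS_PLAN) + len(TRANS_COMP_LENS) + k + 1
        st, nat, rec = plant_decoy(
            genome, chrom, reason, f"ST{idx:04d}", f"DEC{k + 1:04d}", seed=unit_seed()
        )
        transcripts += [st, nat]
        truth.decoys.append(rec)

    # miRNA plants: one mature inside a cis overlap region (S>N, 330-nt
    # overlap -> the whole NAT is overlap), one in the NAT-only extension of
    # a convergent pair.
    mirnas = {"miR156a": MIR156A, "miR-novel": MIR_NOVEL}
    hp1 = plant_mirna_hairpin(
        genome, cis_nats[6], MIR156A, "miR156a", insert_offset=100, seed=unit_seed(),
        star_mismatches=0,
    )
    hp1["in_overlap"] = True
    hp2 = plant_mirna_hairpin(
        genome, cis_nats[4], MIR_NOVEL, "miR-novel", insert_offset=30, seed=unit_seed(),
        star_mismatches=1,
    )
    hp2["in_overlap"] = False
    truth.mirna_plants += [hp1, hp2]
    # hairpin writes changed genomic content under the paired STs too
    by_id = {t.id: t for t in transcripts}
    by_id[truth.cis_pairs[6]["st_id"]].extract(genome)
    by_id[truth.cis_pairs[4]["st_id"]].extract(genome)

    pair_targets = []
    for rec, r in zip(truth.cis_pairs, CIS_TARGET_R):
        pair_targets.append((rec["st_id"], rec["nat_id"], r))
        truth.correlation_targets[f"{rec['st_id']}|{rec['nat_id']}"] = r
    for rec, r in zip(truth.trans_pairs, TRANS_TARGET_R):
        pair_targets.append((rec["st_id"], rec["nat_id"], r))
        truth.correlation_targets[f"{rec['st_id']}|{rec['nat_id']}"] = r
    for rec in truth.decoys:
        pair_targets.append((rec["st_id"], rec["nat_id"], 0.0))
    expression = generate_expression(pair_targets, seed=int(master.integers(2**31)))

    coding_ids = [t.id for t in transcripts if t.biotype == "coding"]
    return Fixture(
        genome=genome,
        transcripts=transcripts,
        coding_ids=coding_ids,
        expression=expression,
        truth=truth,
        mirnas=mirnas,
    )


def emit_fixture(fix: Fixture, out_dir) -> None:
    """Write the fixture as FASTA/GFF3/TSV/JSON files."""
    import os

    from .core_model import write_fasta, write_gff, to_rna

    os.makedirs(out_dir, exist_ok=True)
    write_fasta(fix.genome.contigs, os.path.join(out_dir, "genome.fa"))
    write_gff(fix.transcripts, os.path.join(out_dir, "transcripts.gff3"))
    write_fasta(
        {t.id: t.spliced_seq for t in fix.transcripts},
        os.path.join(out_dir, "transcripts.fa"),
    )
    write_fasta(
        {mid: to_rna(seq) for mid, seq in fix.mirnas.items()},
        os.path.join(out_dir, "mirnas.fa"),
    )
    with open(os.path.join(out_dir, "coding_ids.txt"), "w") as fh:
        fh.write("\n".join(fix.coding_ids) + "\n")
    fix.expression.to_tsv(os.path.join(out_dir, "expression.tsv"))
    fix.truth.to_json(os.path.join(out_dir, "truth.json"))
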