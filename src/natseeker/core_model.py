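"""Domain types and I/O for genome, annotation and expression inputs.

Coordinates are 0-based half-open internally; all file I/O uses the 1-based
inclusive GFF convention.  RNA sequences are normalized to the DNA alphabet
(U -> T) internally; the RNA alphabet is restored only in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result in DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1].replace("a", "t")


def normalize_seq(seq: str) -> str:
    """Uppercase and map U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet, for report output."""
    return seq.upper().replace("T", "U")


class GenomeStore:
    """In-memory contig sequences with stranded interval lookup."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: dict[str, str] = {
            name: normalize_seq(seq) for name, seq in contigs.items()
        }
        for name, seq in self.contigs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} has non-ACGTN characters: {sorted(bad)}")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self.contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > len(self.contigs[chrom]) or start > end:
            raise ValueError(
                f"interval [{start},{end}) outside contig {chrom!r} "
                f"of length {len(self.contigs[chrom])}"
            )
        seq = self.contigs[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq


@dataclass
class Transcript:
    """A stranded, exon-resolved transcript model.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted by start.  ``spliced_seq`` is the mature 5'->3' sequence: for a
    minus-strand transcript it is the reverse complement of the concatenated
    exon genomic sequence.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"
    spliced_seq: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be + or -, got {self.strand!r}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"transcript {self.id}: empty exon [{a},{b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        self.exons = exons
        if self.biotype not in ("coding", "unknown"):
            raise ValueError(f"transcript {self.id}: bad biotype {self.biotype!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def five_prime(self) -> int:
        """Genomic position (0-based) of the 5' terminal base."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Genomic position (0-based) of the 3' terminal base."""
        return self.end - 1 if self.strand == "+" else self.start

    def extract(self, genome: GenomeStore) -> "Transcript":
        """Populate ``spliced_seq`` from the genome; returns self."""
        if self.chrom not in genome:
            raise ValueError(f"transcript {self.id}: contig {self.chrom!r} not in genome")
        clen = genome.length(self.chrom)
        for a, b in self.exons:
            if a < 0 or b > clen:
                raise ValueError(
                    f"transcript {self.id}: exon [{a},{b}) outside contig "
                    f"{self.chrom!r} of length {clen}"
                )
        plus = "".join(genome.fetch(self.chrom, a, b, "+") for a, b in self.exons)
        self.spliced_seq = revcomp(plus) if self.strand == "-" else plus
        return self

    def genomic_to_spliced(self, gpos: int) -> int:
        """Map a genomic position covered by an exon to a spliced coordinate."""
        off = 0
        for a, b in self.exons:
            if a <= gpos < b:
                plus_off = off + (gpos - a)
                return plus_off if self.strand == "+" else self.length - 1 - plus_off
            off += b - a
        raise ValueError(f"position {gpos} not exonic in transcript {self.id}")

    def spliced_intervals(self, start: int, end: int) -> list[tuple[int, int]]:
        """Spliced-coordinate intervals covered by genomic interval [start, end)."""
        out = []
        off = 0
        for a, b in self.exons:
            s, e = max(a, start), min(b, end)
            if s < e:
                out.append((off + s - a, off + e - a))
            off += b - a
        if self.strand == "-":
            n = self.length
            out = [(n - qe, n - qs) for qs, qe in reversed(out)]
        return out


# ---------------------------------------------------------------------------
# GFF3 / GTF

def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    attr = attr.strip().rstrip(";")
    if "=" in attr and '"' not in attr:  # GFF3 dialect
        for part in attr.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
    else:  # GTF dialect: key "value";
        for part in attr.split(";"):
            part = part.strip()
            if not part:
                continue
            bits = part.split(None, 1)
            if len(bits) == 2:
                out[bits[0]] = bits[1].strip().strip('"')
    return out


def _transcript_id_of(attrs: dict[str, str]) -> str | None:
    for key in ("transcript_id", "Parent", "parent"):
        if key in attrs and attrs[key]:
            val = attrs[key]
            # GFF3 Parent may be "transcript:Foo" or a list; take first token
            val = val.split(",")[0]
            if ":" in val:
                val = val.split(":", 1)[1]
            return val
    return None


def read_gff(path, genome: GenomeStore | None = None) -> list[Transcript]:
    """Read exon features from a GFF3 or GTF file into Transcripts.

    1-based inclusive file coordinates are converted to 0-based half-open.
    Records without a strand or a transcript identifier are skipped with a
    logged warning.  If ``genome`` is given, spliced sequences are extracted
    and exons outside contig bounds raise an error naming the record.
    """
    exons_by_tid: dict[str, dict] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9 or fields[2].lower() != "exon":
                continue
            chrom, _src, _type, start, end, _score, strand, _frame, attr = fields[:9]
            if strand not in ("+", "-"):
                logger.warning("line %d: exon without strand evidence skipped", lineno)
                n_skipped += 1
                continue
            tid = _transcript_id_of(_parse_attributes(attr))
            if tid is None:
                logger.warning("line %d: exon lacking a transcript ID skipped", lineno)
                n_skipped += 1
                continue
            iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            rec = exons_by_tid.setdefault(tid, {"chrom": chrom, "strand": strand, "exons": []})
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(f"transcript {tid!r}: exons on mixed contigs/strands")
            rec["exons"].append(iv)
    if n_skipped:
        logger.warning("read_gff: skipped %d exon records", n_skipped)
    transcripts = [
        Transcript(id=tid, chrom=rec["chrom"], strand=rec["strand"], exons=rec["exons"])
        for tid, rec in exons_by_tid.items()
    ]
    transcripts.sort(key=lambda t: t.id)
    if genome is not None:
        for t in transcripts:
            t.extract(genome)
    return transcripts


def write_gff(transcripts: Iterable[Transcript], path) -> None:
    """Write transcripts as GFF3 (transcript + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            fh.write(
                f"{t.chrom}\tnatseeker\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\tID={t.id};biotype={t.biotype}\n"
            )
            for a, b in t.exons:
                fh.write(
                    f"{t.chrom}\tnatseeker\texon\t{a + 1}\t{b}\t.\t"
                    f"{t.strand}\t.\tParent={t.id}\n"
                )


def set_biotypes(transcripts: Iterable[Transcript], coding_ids: Iterable[str]) -> None:
    """Mark transcripts in ``coding_ids`` as coding, the rest as unknown."""
    coding = set(coding_ids)
    for t in transcripts:
        t.biotype = "coding" if t.id in coding else "unknown"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression

class ExpressionMatrix:
    """Transcripts x samples FPKM table with tissue/replicate grouping.

    Sample names follow the ``<replicate>_<tissue>`` convention (e.g.
    ``p01_f``); the tissue label is the suffix after the final underscore.
    """

    def __init__(self, values: pd.DataFrame, sample_groups: Mapping[str, str] | None = None):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript rows: {dups}")
        if (values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values.astype(float)
        if sample_groups is None:
            sample_groups = {s: self._tissue_of(s) for s in values.columns}
        missing = [s for s in values.columns if s not in sample_groups]
        if missing:
            raise ValueError(f"samples without tissue label: {missing}")
        self.sample_groups = dict(sample_groups)

    @staticmethod
    def _tissue_of(sample: str) -> str:
        return sample.rsplit("_", 1)[-1]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen = []
        for s in self.samples:
            t = self.sample_groups[s]
            if t not in seen:
                seen.append(t)
        return seen

    def replicate_index(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == tissue]

    def tissue_means(self) -> pd.DataFrame:
        """Mean FPKM per tissue (over its replicates)."""
        cols = {t: self.values[self.samples_of(t)].mean(axis=1) for t in self.tissues}
        return pd.DataFrame(cols)

    def row(self, transcript_id: str) -> np.ndarray:
        return self.values.loc[transcript_id].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV of FPKMs: first column transcript ID, header = sample names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, int] | pd.Series,
) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (length_nt * library_size), per transcript and sample."""
    lengths = pd.Series(lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing lengths for {lengths[lengths.isna()].index.tolist()}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(libs, axis=1)
    return ExpressionMatrix(fpkm)
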