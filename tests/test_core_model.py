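import logging

import numpy as np
import pandas as pd
import pytest

from natseeker.core_model import (
    ExpressionMatrix,
    GenomeStore,
    Transcript,
    compute_fpkm,
    read_expression,
    read_gff,
    revcomp,
    write_gff,
)


@pytest.fixture()
def contig60():
    rng = np.random.default_rng(3)
    return GenomeStore({"chr1": "".join(rng.choice(list("ACGT"), 60))})


def _gff(tmp_path, lines):
    path = tmp_path / "in.gff3"
    path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
    return path


class TestReadGff:
    def test_one_based_inclusive_coordinates_convert(self, tmp_path, contig60):
        path = _gff(
            tmp_path,
            [
                "chr1\tx\texon\t11\t20\t.\t+\t.\tParent=T1",
                "chr1\tx\texon\t31\t40\t.\t+\t.\tParent=T1",
            ],
        )
        (t,) = read_gff(path, contig60)
        assert t.exons == [(10, 20), (30, 40)]
        assert t.length == 20
        assert t.spliced_seq == contig60.contigs["chr1"][10:20] + contig60.contigs["chr1"][30:40]

    def test_minus_strand_spliced_is_revcomp_three_prime_exon_first(self, tmp_path, contig60):
        path = _gff(
            tmp_path,
            [
                "chr1\tx\texon\t11\t20\t.\t-\t.\tParent=T1",
                "chr1\tx\texon\t31\t40\t.\t-\t.\tParent=T1",
            ],
        )
        (t,) = read_gff(path, contig60)
        g = contig60.contigs["chr1"]
        # 5'-most spliced bases come from the genomic-rightmost exon
        assert t.spliced_seq == revcomp(g[10:20] + g[30:40])
        assert t.spliced_seq[:10] == revcomp(g[30:40])

    def test_exon_without_transcript_id_skipped_with_warning(self, tmp_path, contig60, caplog):
        path = _gff(
            tmp_path,
            [
                "chr1\tx\texon\t11\t20\t.\t+\t.\tID=orphan",
                "chr1\tx\texon\t11\t20\t.\t+\t.\tParent=T1",
            ],
        )
        with caplog.at_level(logging.WARNING):
            ts = read_gff(path, contig60)
        assert [t.id for t in ts] == ["T1"]
        assert any("lacking a transcript ID" in r.message for r in caplog.records)

    def test_missing_strand_rejected_with_warning(self, tmp_path, contig60, caplog):
        path = _gff(tmp_path, ["chr1\tx\texon\t11\t20\t.\t.\t.\tParent=T1"])
        with caplog.at_level(logging.WARNING):
            assert read_gff(path, contig60) == []
        assert any("strand" in r.message for r in caplog.records)

    def test_exon_outside_contig_names_record(self, tmp_path, contig60):
        path = _gff(tmp_path, ["chr1\tx\texon\t55\t120\t.\t+\t.\tParent=T1"])
        with pytest.raises(ValueError, match="T1"):
            read_gff(path, contig60)

    def test_gtf_dialect_accepted(self, tmp_path, contig60):
        path = tmp_path / "in.gtf"
        path.write_text('chr1\tx\texon\t11\t20\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n')
        (t,) = read_gff(path, contig60)
        assert t.id == "T1" and t.exons == [(10, 20)]


def test_gff_round_trip_is_exact(tmp_path, contig60):
    src = _gff(
        tmp_path,
        [
            "chr1\tx\texon\t11\t20\t.\t+\t.\tParent=T1",
            "chr1\tx\texon\t31\t40\t.\t+\t.\tParent=T1",
            "chr1\tx\texon\t5\t25\t.\t-\t.\tParent=T2",
        ],
    )
    ts = read_gff(src, contig60)
    out = tmp_path / "out.gff3"
    write_gff(ts, out)
    ts2 = read_gff(out, contig60)
    assert {(t.id, t.strand, tuple(t.exons)) for t in ts} == {
        (t.id, t.strand, tuple(t.exons)) for t in ts2
    }


def test_spliced_extraction_matches_per_base_oracle(rng):
    """Walking the exons base by base (complementing on -) must reproduce
    the extracted spliced sequence, over random multi-exon transcripts."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    genome = GenomeStore({"c": "".join(rng.choice(list("ACGT"), 2000))})
    g = genome.contigs["c"]
    for k in range(200):
        n = int(rng.integers(1, 5))
        pts = np.sort(rng.choice(np.arange(2000), size=2 * n, replace=False))
        exons = []
        for i in range(n):
            a, b = int(pts[2 * i]), int(pts[2 * i + 1]) + 1
            if exons and a < exons[-1][1]:
                continue
            exons.append((a, b))
        strand = "+" if rng.random() < 0.5 else "-"
        t = Transcript(id=f"t{k}", chrom="c", strand=strand, exons=exons).extract(genome)
        bases = [g[p] for a, b in exons for p in range(a, b)]
        if strand == "-":
            bases = [comp[b] for b in reversed(bases)]
        assert t.spliced_seq == "".join(bases)


class TestTranscriptValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            Transcript(id="t", chrom="c", strand="+", exons=[(0, 10), (5, 15)])

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            Transcript(id="t", chrom="c", strand="*", exons=[(0, 10)])

    def test_termini(self):
        plus = Transcript(id="p", chrom="c", strand="+", exons=[(10, 20)])
        minus = Transcript(id="m", chrom="c", strand="-", exons=[(10, 20)])
        assert (plus.five_prime(), plus.three_prime()) == (10, 19)
        assert (minus.five_prime(), minus.three_prime()) == (19, 10)


class TestExpression:
    def test_groups_parsed_from_sample_suffix(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("transcript_id\tp01_f\tp02_f\tp01_r\nT1\t1\t2\t3\nT2\t0\t0\t9\n")
        m = read_expression(path)
        assert m.sample_groups == {"p01_f": "f", "p02_f": "f", "p01_r": "r"}
        assert m.tissues == ["f", "r"]
        assert m.tissue_means().loc["T1", "f"] == 1.5

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("transcript_id\tp01_f\nT1\t-1\n")
        with pytest.raises(ValueError, match="non-negative"):
            read_expression(path)

    def test_duplicate_transcript_rejected(self):
        df = pd.DataFrame({"p01_f": [1, 2]}, index=["T1", "T1"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(df)


class TestFpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(100, 1000, 10**6, 100.0), (0, 1000, 10**6, 0.0), (50, 500, 10**7, 10.0)],
    )
    def test_formula(self, count, length, lib, expected):
        counts = pd.DataFrame({"s_f": [count]}, index=["T"])
        m = compute_fpkm(counts, {"T": length}, {"s_f": lib})
        assert m.values.loc["T", "s_f"] == pytest.approx(expected)

    def test_zero_length_or_library_rejected(self):
        counts = pd.DataFrame({"s_f": [1]}, index=["T"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, {"T": 0}, {"s_f": 10})
        with pytest.raises(ValueError):
            compute_fpkm(counts, {"T": 100}, {"s_f": 0})


def test_revcomp_normalizes_rna():
    assert revcomp("AUGC") == "GCAT"
    assert revcomp("ACGTN") == "NACGT"
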