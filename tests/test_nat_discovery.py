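import numpy as np
import pandas as pd
import pytest

from oracles import per_base_overlap, smith_waterman_score

from natseeker import alignment
from natseeker import synthetic_data as sd
from natseeker.core_model import ExpressionMatrix, Transcript, revcomp
from natseeker.nat_discovery import (
    AnnealingResult,
    SATPair,
    ComplementaryRegion,
    assess_annealing,
    candidate_condition,
    discover,
    filter_expressed,
    find_cis_candidates,
)


def _expr(rows: dict) -> ExpressionMatrix:
    cols = ["p01_f", "p01_l", "p01_r"]
    return ExpressionMatrix(pd.DataFrame(rows, index=cols).T)


def _transcript(tid, length=1000):
    return Transcript(id=tid, chrom="c", strand="+", exons=[(0, length)])


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "means,kept",
        [((0.5, 0.8, 0.9), False), ((0.0, 1.2, 0.0), True), ((1.0, 0.0, 0.0), True)],
    )
    def test_tissue_mean_cutoff(self, means, kept):
        m = _expr({"T": list(means)})
        out = filter_expressed([_transcript("T")], m, cutoff=1.0)
        assert bool(out) is kept

    def test_cutoff_zero_keeps_everything(self):
        m = _expr({"T": [0.0, 0.0, 0.0]})
        assert filter_expressed([_transcript("T")], m, cutoff=0.0)

    def test_absent_transcripts_dropped(self):
        m = _expr({"T": [5, 5, 5]})
        out = filter_expressed([_transcript("T"), _transcript("X")], m)
        assert [t.id for t in out] == ["T"]


class TestCisCandidates:
    def test_planted_convergent_pair_yields_single_region(self, toy_genome):
        st, nat, rec = sd.plant_cis_pair(toy_genome, "chr1", "convergent", 150, "S", "N", seed=1)
        (pair,) = find_cis_candidates([st, nat])
        assert pair.category == "cis"
        assert [r.length for r in pair.regions] == [150]
        assert pair.regions[0].genomic_interval == tuple(rec["overlap_regions"][0])

    def test_same_strand_overlap_is_not_a_pair(self):
        a = Transcript(id="a", chrom="c", strand="+", exons=[(0, 500)], biotype="coding")
        b = Transcript(id="b", chrom="c", strand="+", exons=[(100, 700)], biotype="unknown")
        assert find_cis_candidates([a, b]) == []

    def test_four_segment_overlap_recovered(self, toy_genome):
        st, nat, rec = sd.plant_cis_pair(
            toy_genome, "chr1", "S>N", 1, "S", "N", seed=2,
            exon_plan=sd.FOUR_SEGMENT_PLAN,
        )
        (pair,) = find_cis_candidates([st, nat])
        assert [r.length for r in pair.regions] == [181, 38, 165, 49]

    def test_regions_match_per_base_oracle(self, rng):
        """Merged exon-intersection regions equal the per-base marking oracle
        on random opposite-strand transcript pairs."""
        from conftest import random_transcript_pair

        checked = 0
        for _ in range(300):
            st, nat = random_transcript_pair(rng)
            pairs = find_cis_candidates([st, nat])
            expected = per_base_overlap(st, nat)
            if not expected:
                assert pairs == []
                continue
            checked += 1
            (pair,) = pairs
            assert [r.genomic_interval for r in pair.regions] == expected
        assert checked > 50


class TestCandidateCondition:
    def _pair(self, st_len, nat_len, region_lengths):
        regions = [
            ComplementaryRegion((0, n), (0, n), n, 1.0, "genomic_overlap")
            for n in region_lengths
        ]
        return SATPair("s", "n", "cis", regions, st_len, nat_len)

    def test_half_of_shorter_transcript_suffices(self):
        assert candidate_condition(self._pair(1000, 400, [250]))

    def test_neither_condition_met(self):
        assert not candidate_condition(self._pair(2000, 2000, [99, 60]))

    def test_region_of_exactly_100_accepted(self):
        assert candidate_condition(self._pair(2000, 2000, [100]))


class TestComplementAlign:
    def test_self_complement_covers_everything(self, rng):
        q = "".join(rng.choice(list("ACGT"), 300))
        (hit,) = alignment.complement_align(q, revcomp(q))
        assert (hit.q_start, hit.q_end) == (0, 300)
        assert hit.identity == 1.0

    def test_independent_random_kilobases_do_not_align(self):
        r = np.random.default_rng(11)
        a = "".join(r.choice(list("ACGT"), 1000))
        b = "".join(r.choice(list("ACGT"), 1000))
        hits = alignment.complement_align(a, b)
        assert all(h.length < 100 for h in hits)

    def test_planted_degraded_region_recovered(self, toy_genome):
        st, nat, rec = sd.plant_trans_pair(toy_genome, "chr1", 200, 0.95, [], "S", "N", seed=3)
        hits = alignment.complement_align(st.spliced_seq, nat.spliced_seq)
        assert hits
        h = hits[0]
        s0, s1 = rec["st_region"]
        covered = max(0, min(h.q_end, s1) - max(h.q_start, s0))
        assert covered >= 180

    def test_score_equals_smith_waterman_on_seeded_instances(self, rng):
        """With a shared word present, the reported score is the exact
        affine local-alignment optimum (gap k costs 5+2k)."""
        for k in range(10):
            q = "".join(rng.choice(list("ACGT"), 250))
            core = q[60:200]
            sub = (
                "".join(rng.choice(list("ACGT"), 40))
                + revcomp(core)
                + "".join(rng.choice(list("ACGT"), 40))
            )
            hits = alignment.complement_align(q, sub)
            expected = smith_waterman_score(q, revcomp(sub))
            assert hits and hits[0].score == expected

    def test_score_never_exceeds_smith_waterman(self, rng):
        for k in range(5):
            q = "".join(rng.choice(list("ACGT"), 800))
            sub = "".join(rng.choice(list("ACGT"), 800))
            hits = alignment.seeded_local_align(q, sub, min_score=10)
            bound = smith_waterman_score(q, sub)
            assert all(h.score <= bound for h in hits)


class TestAnnealing:
    def test_perfect_duplex_passes(self, rng):
        s = "".join(rng.choice(list("ACGT"), 200))
        r = assess_annealing(s, revcomp(s))
        assert (r.annealed_fraction, r.bubbles, r.pass_) == (1.0, [], True)

    def test_large_bubble_fails(self, toy_genome):
        st, nat, rec = sd.plant_trans_pair(toy_genome, "chr1", 200, 1.0, [(100, 30)], "S", "N", seed=5)
        s0, s1 = rec["st_region"]
        n0, n1 = rec["nat_region"]
        r = assess_annealing(st.spliced_seq[s0:s1], nat.spliced_seq[n0:n1])
        assert r.max_bubble_fraction == pytest.approx(0.15)
        assert not r.pass_

    def test_low_annealed_fraction_fails(self, toy_genome):
        bubbles = [(20, 10), (60, 10), (100, 10), (140, 10), (180, 10)]
        st, nat, rec = sd.plant_trans_pair(toy_genome, "chr1", 200, 1.0, bubbles, "S", "N", seed=5)
        s0, s1 = rec["st_region"]
        n0, n1 = rec["nat_region"]
        r = assess_annealing(st.spliced_seq[s0:s1], nat.spliced_seq[n0:n1])
        assert r.annealed_fraction == pytest.approx(0.75)
        assert not r.pass_ and r.max_bubble_fraction < 0.1

    def test_pass_invariant_under_role_swap(self, rng):
        for _ in range(20):
            n = int(rng.integers(120, 260))
            s = "".join(rng.choice(list("ACGT"), n))
            t = list(revcomp(s))
            for k in rng.choice(np.arange(n), size=int(rng.integers(0, n // 4)), replace=False):
                t[k] = "ACGT"[int(rng.integers(4))]
            t = "".join(t)
            a, b = assess_annealing(s, t), assess_annealing(t, s)
            assert (a.pass_, a.annealed_len, a.bubbles) == (b.pass_, b.annealed_len, b.bubbles)

    def test_result_invariants(self):
        r = AnnealingResult(annealed_len=150, comp_len=200, bubbles=[(10, 12)])
        assert 0 <= r.annealed_fraction <= 1
        assert r.max_bubble_fraction == pytest.approx(0.06)


class TestDiscover:
    def test_empty_transcript_set(self):
        assert discover([]) == []

    def test_weak_complement_excluded(self, toy_genome):
        st, nat, _ = sd.plant_trans_pair(toy_genome, "chr1", 80, 1.0, [], "S", "N", seed=9)
        assert discover([st, nat]) == []

    def test_fixture_recovery(self, default_fix, discovered_pairs):
        """All planted pairs are discovered before noncoding filtering;
        decoy trans couples are rejected by the candidate conditions."""
        found = {(p.st_id, p.nat_id) for p in discovered_pairs}
        assert default_fix.truth.pair_keys <= found
        weak = {
            (d["st_id"], d["nat_id"])
            for d in default_fix.truth.decoys
            if d["reason"] == "weak_complement"
        }
        assert not (weak & found)
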