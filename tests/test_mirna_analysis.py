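import numpy as np
import pytest

from oracles import enumerate_max_pairs

from natseeker import synthetic_data as sd
from natseeker.core_model import Transcript, revcomp
from natseeker.mirna_analysis import (
    count_pairs,
    evaluate_precursor,
    find_mirna_origins,
    fold_region,
    scan_targets,
)

MATURE = "UGACAGAAGAGAGUGAGCAC"  # 20 nt


def _st_with_site(site_offset=50, flank=200, mutate=None):
    """An ST whose spliced sequence carries a target site (revcomp of the
    mature) at the given offset; optional position->base mutations are in
    miRNA coordinates (1 = mature 5' end)."""
    rng = np.random.default_rng(99)
    mature = MATURE.replace("U", "T")
    site = list(revcomp(mature))
    L = len(mature)
    for pos, base in (mutate or {}).items():
        site[L - pos] = base  # miRNA position i pairs site base L - i
    seq = (
        "".join(rng.choice(list("ACGT"), site_offset))
        + "".join(site)
        + "".join(rng.choice(list("ACGT"), flank))
    )
    return Transcript(id="ST", chrom="c", strand="+", exons=[(0, len(seq))], spliced_seq=seq)


class TestScanTargets:
    def test_perfect_site_scores_zero_and_cleaves(self):
        st = _st_with_site()
        hits = scan_targets(MATURE, st, overlap_regions=[(40, 120)])
        assert len(hits) == 1
        h = hits[0]
        assert h.expectation == 0.0
        assert h.inhibition == "cleavage"
        assert h.site_interval == (50, 70)
        assert h.in_overlap

    def test_wobble_outside_seed_costs_half(self):
        # miRNA position 15 is G; target T gives a G:U wobble, weight x1
        assert MATURE[14] == "G"
        st = _st_with_site(mutate={15: "T"})
        (h,) = scan_targets(MATURE, st)
        assert h.expectation == 0.5
        assert h.inhibition == "cleavage"

    def test_central_mismatch_calls_translation_inhibition(self):
        st = _st_with_site(mutate={10: "A"})  # position 10 pairs A:A -> mismatch
        (h,) = scan_targets(MATURE, st)
        assert h.inhibition == "translation"
        assert h.expectation == 2.0  # doubled inside positions 2-13

    def test_seed_doubling_applies_to_positions_2_to_13(self):
        inside = _st_with_site(mutate={5: "C"})  # A at miRNA pos 5 -> A:C mismatch
        outside = _st_with_site(mutate={15: "C"})  # G:C is a match... use A
        (h_in,) = scan_targets(MATURE, inside)
        assert h_in.expectation == 2.0
        st = _st_with_site(mutate={16: "C"})  # pos 16 is U; U:C mismatch, weight x1
        (h_out,) = scan_targets(MATURE, st)
        assert h_out.expectation == 1.0

    def test_site_outside_overlap_flagged(self):
        st = _st_with_site(site_offset=100)
        (h,) = scan_targets(MATURE, st, overlap_regions=[(0, 50)])
        assert not h.in_overlap

    def test_mature_length_validated(self):
        st = _st_with_site()
        with pytest.raises(ValueError, match="18-26"):
            scan_targets("ACGU" * 10, st)


class TestFindMirnaOrigins:
    def _nat(self, seq):
        return Transcript(id="NAT", chrom="c", strand="+", exons=[(0, len(seq))], spliced_seq=seq)

    def test_planted_locus_reported(self, rng):
        mature = MATURE.replace("U", "T")
        seq = sd.stopful_seq(rng, 240) + mature + sd.stopful_seq(rng, 100)
        hits = find_mirna_origins({"m": MATURE}, [self._nat(seq)])
        assert any(h["offset"] == 240 and h["mismatches"] == 0 for h in hits)

    def test_absent_mature_gives_nothing(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        hits = find_mirna_origins({"m": MATURE}, [self._nat(seq)])
        # a 20-mer match (even 1 mismatch) in 400 random nt is essentially impossible
        assert hits == []

    def test_mismatch_tolerance_matches_hamming_oracle(self, rng):
        """One planted mismatch is still found; two are not — as a sliding-
        window Hamming scan predicts."""
        mature = MATURE.replace("U", "T")
        for n_mm, expect_found in [(1, True), (2, False)]:
            probe = list(mature)
            for k in range(n_mm):
                pos = 4 + 7 * k
                probe[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[probe[pos]]
            seq = sd.stopful_seq(rng, 150) + "".join(probe) + sd.stopful_seq(rng, 150)
            hits = find_mirna_origins({"m": MATURE}, [self._nat(seq)])
            oracle = min(
                sum(a != b for a, b in zip(mature, seq[o : o + 20]))
                for o in range(len(seq) - 19)
            )
            assert (oracle <= 1) is expect_found
            assert bool([h for h in hits if h["orientation"] == "sense"]) is expect_found

    def test_overlap_membership_reported(self, rng):
        mature = MATURE.replace("U", "T")
        seq = sd.stopful_seq(rng, 100) + mature + sd.stopful_seq(rng, 100)
        hits = find_mirna_origins(
            {"m": MATURE}, [self._nat(seq)], overlap_regions={"NAT": [(90, 140)]}
        )
        assert hits and hits[0]["in_overlap"]


class TestFoldRegion:
    def test_unique_maximum_hairpin(self):
        assert fold_region("GGGAAACCC") == "(((...)))"

    def test_unpairable_sequence_stays_open(self):
        assert fold_region("A" * 30) == "." * 30

    def test_minimum_loop_enforced(self):
        assert fold_region("GAAC") == "...."  # 2 unpaired between: too tight
        assert fold_region("GAAAC") == "(...)"  # 3 unpaired: smallest legal loop

    def test_long_input_rejected(self):
        with pytest.raises(ValueError, match="400"):
            fold_region("A" * 401)

    def test_pair_count_matches_enumeration_oracle(self, rng):
        """Exact DP optimality on every tested short sequence."""
        for _ in range(150):
            n = int(rng.integers(5, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            assert count_pairs(fold_region(seq)) == enumerate_max_pairs(seq)

    def test_structure_is_well_nested(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 80))
        s = fold_region(seq)
        depth = 0
        for c in s:
            depth += {"(": 1, ")": -1}.get(c, 0)
            assert depth >= 0
        assert depth == 0


class TestEvaluatePrecursor:
    def _planted(self, star_mismatches=0, seed=11):
        rng = np.random.default_rng(seed)
        genome = sd.GenomeStore({"chr1": sd.rand_seq(rng, 6000)})
        nat = Transcript(id="N", chrom="chr1", strand="+", exons=[(100, 500)]).extract(genome)
        nat.spliced_seq = sd.stopful_seq(rng, 400)
        rec = sd.plant_mirna_hairpin(
            genome, nat, MATURE, "m", insert_offset=120, seed=seed,
            star_mismatches=star_mismatches,
        )
        return nat, rec

    def test_planted_hairpin_passes_with_mature_mostly_paired(self):
        nat, rec = self._planted(star_mismatches=0)
        rep = evaluate_precursor(nat, (rec["offset"], rec["offset"] + rec["length"]))
        assert rep.pass_
        assert rep.mature_paired >= 19
        assert rep.arm == "5p"

    def test_mature_straddling_the_loop_fails(self):
        nat, rec = self._planted()
        # shift the claimed locus so it spans mature 3' end, the loop and star
        start = rec["offset"] + 12
        rep = evaluate_precursor(nat, (start, start + 20))
        assert not rep.pass_

    def test_insufficient_flank(self):
        nat, rec = self._planted()
        short = Transcript(
            id="S", chrom="c", strand="+", exons=[(0, 30)],
            spliced_seq=nat.spliced_seq[rec["offset"] - 5 : rec["offset"] + 25],
        )
        rep = evaluate_precursor(short, (5, 25))
        assert not rep.pass_ and rep.reason == "insufficient flank"

    def test_mature_with_n_rejected_by_planter(self, rng):
        genome = sd.GenomeStore({"chr1": sd.rand_seq(rng, 6000)})
        nat = Transcript(id="N", chrom="chr1", strand="+", exons=[(100, 500)]).extract(genome)
        with pytest.raises(ValueError, match="ACGU"):
            sd.plant_mirna_hairpin(genome, nat, "ACGUN" * 4, "m", insert_offset=100, seed=1)
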