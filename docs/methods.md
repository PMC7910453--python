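# Methods

This note documents the models, algorithms and numerical choices behind
`natseeker`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real data.

## Coordinates, alphabets, conventions

All interval arithmetic is 0-based half-open internally; GFF3/GTF I/O uses
the standard 1-based inclusive convention, converted once at the boundary.
RNA input (miRNAs, U-containing sequences) is normalized to the DNA
alphabet internally and restored to RNA in reports. `N` never matches or
pairs in any alignment or duplex. A minus-strand spliced sequence is the
reverse complement of the exon concatenation in genomic order, so its
5'-most bases come from the genomic-rightmost exon. Exon features lacking
strand evidence are rejected with a logged warning: antisense calls are
meaningless without strand, so guessing would be worse than dropping.

## Discovery model

A SAT pair couples a protein-coding sense transcript (ST) with a
noncoding-candidate transcript on the antisense. Candidate status at
discovery time comes from the annotation (the coding-ID list); final
noncoding status is decided by the filter cascade, so a candidate that
turns out to code is removed together with its pairs.

**cis pairs** require same contig, opposite strands and ≥ 1 bp of
exon-level overlap. Overlap regions are exact interval intersections of
the two exon chains; identity is 1 by construction, and no annealing check
is run (a genomic overlap is perfectly complementary).

**trans pairs** must show sequence complementarity between loci. The
aligner requires an exact shared 11-mer between the ST and the reverse
complement of the candidate as a seed, then computes the exact optimal
affine local alignment (match +1, mismatch −2; a gap of length k costs
5 + 2k). The seed requirement makes the all-vs-all scan cheap and mirrors
word-seeded search behavior; whenever a seed exists, the reported score is
the true Smith–Waterman optimum (verified against an independent full-DP
oracle in the tests). No E-value statistics are computed: a raw score
threshold (default 50) stands in, calibrated so that independent random
kilobase sequences produce no reportable alignment. Up to three
non-overlapping (on the query) alignments are reported per couple and
their merged lengths feed the candidate conditions.

**Candidate conditions.** A pair qualifies when the summed region length
exceeds half of *at least one* transcript's spliced length, or a single
region is ≥ 100 nt. The "at least one" reading is deliberate: requiring
both would exclude the common case of a short NAT overlapping a long ST.
Both thresholds are boundary-tested (exactly 100 nt is accepted).

**Annealing.** The duplex model is base-pair maximization between the two
region sequences — Watson–Crick plus G:U wobble, antiparallel,
non-crossing, no intra-strand pairing — rather than a thermodynamic free
energy. The pass criteria only involve pairing geometry (coverage and
bubbles), so a free-energy model would add parameters without changing the
decision structure. A pair passes when the annealed span is coincident
with the complementary region (≤ 5 nt slack at each end), covers strictly
more than 80 % of it, and every internal bubble (the larger of the two
strands' unpaired runs between consecutive pairs) is strictly shorter than
10 % of the region. Both inequalities are strict and boundary-tested
(0.80 and 0.10 fail). The result is invariant to swapping the ST and NAT
roles: the two sequences are canonicalized (sorted) before the DP, since
mirrored problems can otherwise break ties differently and report
different bubble layouts.

## Noncoding filter

A candidate NAT is kept iff all of: spliced length ≥ 200 nt; longest
ATG-initiated, stop-terminated reading frame on its own strand has a
start-through-stop span < 300 nt (the 100-aa rule; the coding-region
length excluding the stop is reported alongside); no protein-database hit;
no coding-potential score > 0. The last two are *evidence hooks* — a TSV
of externally computed booleans/scores — because protein-database and
coding-potential results depend on database versions and are not
reproducible in-repo. An absent hook is treated as no evidence. The score
rule is strictly greater than zero: a score of exactly 0 keeps the NAT.
The four rules are independent, so the kept set is order-independent
(tested). Unterminated open frames at the sequence end do not count,
matching start-to-stop ORF-scanning semantics.

## Characterization

Positional types for cis pairs are read from genomic span geometry:
containment first (N>S when the NAT span contains the ST span, S>N for the
converse; identical spans resolve to S>N with a logged note), then
convergent when the span overlap contains both 3' termini, divergent when
it contains both 5' termini. Containment is checked on spans, not exon
unions, matching how these classes are drawn in the field; overlap
*fractions* are computed on spliced (exonic) totals since they are
compared with transcript lengths. Relationship labels per pair come from
the degrees of its NAT (d_N = number of STs it maps to) and its ST
(d_S = number of NATs on it): 1v1, 1vn (d_N > 1), nv1 (d_S > 1), nvn
(both). Every pair gets a label; positional counts sum to the cis-pair
count (conservation is asserted in the pipeline summary).

The conservation scan is the same seeded aligner run same-strand with word
size 7; a hit is reported only when the aligned span covers ≥ 50 % of both
sequences, which is the binding constraint in practice — the score
threshold only suppresses spurious seeds.

## Expression analyses

Co-expression is the sample Pearson correlation of NAT and ST FPKM
profiles over **all replicate samples** (nine in the three-tissue,
three-replicate design), not tissue means — replicates carry real
information about within-tissue covariation. Significance is the standard
two-sided t-test on r; q-values are Benjamini–Hochberg across all tested
pairs. Classes: `positive_high` (r ≥ 0.9), `positive`, `negative`;
zero-variance profiles yield NaN and are flagged, never coerced to 0.

Differential expression is a Welch t-test on log2(FPKM + 1) replicate
values with log2FC computed from tissue means under a 1-FPKM pseudocount
(bounded fold changes on zero-containing rows, consistent with the FPKM ≥ 1
expression floor), and the decision rule |log2FC| ≥ 1 ∧ q ≤ 0.05. This
does not model count overdispersion; with FPKM-level input and n = 3 it is
mildly conservative (the permuted-label type-I rate measured by the tests
is well under 5 %).

ΔCt utilities implement ΔCt = Ct[X] − Ct[reference] and relative level
2^−ΔCt; correlation analyses on qPCR data use ΔCt directly (Ct is already
a log-scale quantity).

## miRNA layer

Target scanning slides the reverse complement of the mature miRNA along
the ST (gapless; plant miRNA sites are canonically near-perfect, so gapped
search would only add parameters — the gap penalty of 2 is defined for
completeness). Position 1 is the mature 5' end; per-position penalties are
mismatch 1, G:U wobble 0.5, doubled at positions 2–13; hits require
expectation ≤ 5 (configurable). A true mismatch (not a wobble) at
positions 9–11 calls translational inhibition, otherwise cleavage. Each
hit records whether it intersects a NAT-overlap region, since duplex
masking is only plausible there.

Folding is Nussinov base-pair maximization (WC + G:U, minimum hairpin loop
3 nt, no pseudoknots) with a deterministic traceback: pairing (i, j) is
preferred over bifurcation on ties, then the leftmost split. Pair counts
are exactly optimal (verified against exhaustive enumeration on all tested
short sequences). Energy-based folding is out of scope because the
precursor criteria used here depend only on pairing topology.

A candidate precursor (a ≤ 1-mismatch mature match inside a NAT, searched
in both orientations) is evaluated on the mature ± 150 nt window: it
passes when (a) no partner of a mature base lies inside the mature and all
partners fall on one side (the arm), (b) the region enclosed by the
innermost mature pair continues as a single stem/terminal loop rather than
branching into multiple helices — a multiloop is not a hairpin arm, and
without this clause pair-maximization lets a sizable fraction of shuffled
controls pair the mature against a distant pseudo-star; (c) at most 5
mature positions are unpaired; and (d) no bulge in the mature:star duplex
(unpaired run on either strand between consecutive mature pairs) exceeds
3 nt. Windows shorter than mature + 30 nt fail with reason
"insufficient flank".

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-condition definition, not a tuning
surface. The default fixture plants, per seed: 12 cis pairs (three per
positional type, overlaps 101–500 nt, one pair with the four-segment
overlap pattern 181/38/165/49 nt), 12 trans pairs (complementary regions
150–400 nt, identities 0.95–1.0), and 20 decoys that each violate exactly
one retention rule (7 with a planted 402-nt-span ORF, 7 shorter than
200 nt, 6 with only an 80-nt complementary region). STs carry a planted
402-nt ORF wherever the geometry leaves room (an N>S ST shorter than
414 nt is coding by annotation only). Sequence destined to be a NAT is
generated stop-rich — a TAAATAAATAA block (one stop per frame) at most
every 70 nt — and every write over a NAT is followed by a verify-and-repair
loop against the ORF scanner, so planted NATs cannot be lost to the coding
filter by accident. Planted bubbles are homopolymer constructions (a T-run
facing a C-run) that cannot pair in or out of register, giving exact
boundary cases for the annealing rules.

Expression is drawn on the log2 scale: per pair, tissue effects
(SD 0.8 ≈ up to ~4-fold tissue swings) and replicate noise (SD 0.4 ≈ 30 %
CV) share one latent correlation, then values are exponentiated to FPKM.
The latent correlation is corrected for the lognormal transform so the
*expected Pearson r of the FPKM values* equals the requested target; with
these variances the correction is exact for targets down to about −0.6
(stronger negative targets saturate toward the attainable minimum and are
clamped with a warning). Every transcript is rescaled, if needed, so its
best tissue mean reaches 4 FPKM — a pure scaling that leaves Pearson
correlations untouched while guaranteeing the expression filter sees every
planted transcript. Hairpin plants insert a 5' extension arm (35 nt),
mature, 18-nt loop, a star with ≤ 2 mismatches, and the arm's reverse
complement; the insert is re-drawn until the precursor passes and the NAT
stays ORF-free.

Passing on this fixture demonstrates correctness of the interval, alignment,
duplex, filtering, classification and calibration machinery under known
truth. It does **not** demonstrate robustness to real-data phenomena the
generator omits: assembly fragmentation and chimeras, repeat- and
paralog-induced spurious trans hits, polyadenylation bias against
non-polyA NATs, FPKM estimation noise from multi-mapping reads, or GC- and
length-dependent coverage bias.

## Problem sizes and determinism

The default fixture (44 contigs × 6 kb, 88 transcripts) builds in ~2 s and
the full pipeline runs in ~10 s on one CPU; oracle test batteries use
1,000 random transcript pairs (overlap), 500 kilobase sequences (ORF), 500
short sequences (folding) and 200-replicate Monte-Carlo calibrations —
sizes chosen so the whole suite completes in about a minute while keeping
binomial confidence intervals narrow relative to the calibration bands.
All randomness flows through explicit integer seeds (no global RNG state);
rerunning any stage with the same seed is byte-identical, and the summary
JSON serializes every threshold for provenance.

## Known limitations

- No E-value model for the alignment steps; score thresholds are
  fixture-calibrated, so sensitivity on genomes with very different base
  composition may differ.
- The duplex and folding models maximize pair counts; AU-rich and
  wobble-rich helices are treated as strongly as GC helices.
- The DE test assumes approximate log-normality of FPKM within groups.
- The coding filter sees only ATG-initiated frames on the given strand;
  non-AUG starts and selenoproteins are invisible.
- Trans discovery is all-vs-all per (coding, candidate) couple; for
  transcriptomes far beyond ~10^4 candidates an indexed prefilter would be
  needed.
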