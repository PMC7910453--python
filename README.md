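# natseeker

Genome-wide identification and characterization of **natural antisense
transcripts (NATs)** from strand-specific transcriptome assemblies.

NATs are long noncoding RNAs transcribed opposite to protein-coding genes
(their *sense transcripts*, STs). They regulate gene expression through
RNA–RNA duplex formation, transcriptional interference, chromatin
modification, and by masking or producing miRNAs. `natseeker` is for
researchers who have a genome, a stranded exon-resolved transcript
annotation, and an expression matrix, and want a reproducible, fully
scripted NAT census with planted-truth validation.

## What it computes

Given transcripts *t* with spliced lengths *L(t)* and FPKM expression:

1. **Expression filter** — keep transcripts with FPKM ≥ 1 in at least one
   tissue (mean over replicates).
2. **Candidate SAT pairs** (ST–NAT pairs). A couple (coding ST, noncoding
   candidate) qualifies when its complementary region satisfies
   Σ|region| > 0.5·min(L(ST), L(NAT)) **or** max|region| ≥ 100 nt.
   - *cis*: opposite strands, same locus; regions are exact exon-level
     genomic intersections.
   - *trans*: different loci; regions come from a seeded local alignment of
     the ST against the reverse complement of the candidate (match +1,
     mismatch −2, gap of length *k* costs 5+2*k*), and the pair must
     **anneal**: a base-pair–maximization duplex (Watson–Crick + G:U) over
     the complementary region must cover > 80 % of it with every internal
     bubble < 10 % of the region.
3. **Noncoding filter** — a NAT is retained iff *L* ≥ 200 nt, its longest
   ATG→stop span is < 300 nt (100 aa) on its own strand, and optional
   external evidence hooks report no protein-database hit and no
   coding-potential score > 0.
4. **Characterization** — positional types for cis pairs (convergent,
   divergent, S>N, N>S), relationship multiplexing (1v1 / 1vn / nv1 / nvn)
   from the bipartite NAT–ST graph, overlap fractions, length/exon
   summaries, and an optional conservation scan against a user-provided
   lncRNA FASTA (word size 7, ≥ 50 % coverage of both sequences).
5. **Expression analyses** — Pearson co-expression of NAT/ST profiles over
   all replicate samples with BH-FDR (r ≥ 0.9 ⇒ `positive_high`);
   differential expression by Welch t-test on log2(FPKM+1) with the
   |log2FC| ≥ 1 ∧ q ≤ 0.05 decision rule; ΔCt utilities for qPCR data
   (ΔCt = Ct[X] − Ct[reference], relative level 2^−ΔCt).
6. **miRNA layer** — target-site scan of STs restricted to NAT-overlap
   regions (penalty: mismatch 1, G:U 0.5, doubled at miRNA positions 2–13,
   expectation ≤ 5), and pri-miRNA detection in NATs: mature-match loci are
   folded (Nussinov base-pair maximization, min loop 3 nt) and the hairpin
   passes when the mature sits fully on one arm with ≤ 5 unpaired
   positions and no duplex bulge > 3 nt.

A seeded synthetic-data module generates genomes with planted cis pairs of
all four positional types, trans pairs with controlled complementary
length/identity/bubbles, coding and short and weak-complement decoys,
tissue-replicate expression with planted correlations, and miRNA hairpins —
so every stage is testable against known truth.

## Worked example

Run the full pipeline on the built-in synthetic fixture (a genome carrying
12 planted cis pairs, 12 planted trans pairs and 20 decoys):

```bash
natseeker run-all --seed 42 --out demo_out
```

which prints the stage counts:

```json
{
  "candidates_total": 38,
  "cis_candidates": 26,
  "cis_condition_kept": 26,
  "cis_condition_removed": 0,
  "cis_nat_pct_of_coding": 27.27,
  "coding_expressed": 44,
  "filter_kept": 24,
  "filter_removed": 14,
  "final_cis": 12,
  "final_cis_nats": 12,
  "final_pairs": 24,
  "final_trans": 12,
  "final_trans_nats": 12,
  "trans_aligned": 18,
  "trans_annealed_fail": 0,
  "trans_annealed_pass": 12,
  "trans_condition_kept": 12,
  "trans_condition_removed": 6,
  "trans_nat_pct_of_coding": 27.27,
  "transcripts_expressed": 88,
  "transcripts_total": 88
}
```

Reading: of 88 expressed transcripts, 26 cis couples overlap on opposite
strands and 18 trans couples align against a reverse complement; the
candidate conditions discard the 6 weak-complement decoy couples, and the
noncoding filter removes the 14 candidate pairs whose "NAT" carries a
planted ORF or is shorter than 200 nt. The 24 surviving pairs are exactly
the 24 planted ones (12 cis + 12 trans); `demo_out/pairs.tsv` lists each
with its overlap regions, annealing metrics and positional/relationship
labels, and `demo_out/summary.json` records every threshold used.

The same stages are available individually (`natseeker simulate`,
`discover`, `filter`, `characterize`, `express`, `mirna`) on your own
FASTA/GFF3/TSV inputs.

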