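# mek — plant microexon discovery, modeling and splicing analysis

The smallest internal exons — microexons of 1–15 nt — are routinely missed
or misannotated by genome annotation pipelines because standard gene
predictors need more sequence than a microexon contains, and short-read
aligners struggle to split a read across two introns separated by only a
few matched bases. In plants, where the dominant form of alternative
splicing is intron retention, the introns flanking microexons are also of
special interest: many are *detained introns* that remain unspliced in
polyadenylated chromatin-bound transcripts and are only removed
post-transcriptionally.

`mek` is a toolkit for this problem domain. It works from spliced
alignments (SAM), genome sequence (FASTA) and annotations (GTF/GFF3), and
provides:

- **Spanning-read detection** — a microexon-spanning read is a uniquely
  mapped read whose CIGAR contains an `M,N,M,N,M` run: a ≥ 6-nt anchor in
  the 5′ flanking exon, an intron gap, a 1–15 nt match covering the entire
  microexon, a second intron gap, and a ≥ 6-nt 3′ anchor, with intron gaps
  in [20, 20000] nt.
- **Microexon calling** — candidate microexons are 1–15 nt gaps between a
  pair of canonical (GT-AG / GC-AG) introns; a call requires ≥ 5 junction
  reads on *both* flanking introns in at least one sample, with competing
  alternative introns resolved by the highest mean junction count across
  the sample population. Inclusion is quantified as percent spliced-in,
  `PSI = I / (I + E)`, with `I` the mean of the two inclusion-junction
  counts and `E` the count of the exclusion junction joining the flanking
  exons directly. Calls are classified against an annotation
  (exact / inside a larger exon / intronic / unannotated), and annotated
  microexons without junction support are flagged.
- **Intron-retention statistics** — per intron and sample,
  `PIR = 100 (i1 + i2) / (i1 + i2 + 2e + 2o)` from boundary-spanning
  (`i1`, `i2`), exact spliced (`e`) and other gapped (`o`) reads, each
  extending ≥ 4 nt from the boundary; PIR is missing below 10 junction
  reads. Replicate-averaged unspliced ratios (PIR/100) across chromatin
  (CB), nucleoplasm and cytoplasm fractions classify detained introns
  (CB ratio > 0.1, constitutively spliced in the cytoplasm: ratio < 0.2).
  Sliding windows count U(T)-rich (> 80% T in 20 nt) and G-rich
  (> 80% G in 10 nt) intronic-splicing-enhancer signals, contrasted by
  Pearson's chi-squared test.
- **Microexon-tags and clustering** — a 108-nt in-frame coding window
  centered on the microexon (truncated in frame at ORF ends) translates to
  a 36-aa peptide; tags are grouped by microexon size and phase
  (CDS offset mod 3) and clustered by global BLOSUM62 peptide alignment
  score (complete linkage, every within-cluster pair ≥ 50, ≥ 3 species).
- **Split-PWM genome modeling** — each cluster's unique tag DNAs give a
  position weight matrix that is split at the cluster's exon boundaries
  into a microexon part and flanking parts; parts are scanned over both
  genome strands and chained, allowing no gap or an intron gap of
  20 bp–10 kb bounded by GT/GC..AG. A locus whose microexon part keeps
  both flanking introns is a **microexon**; one with a missing gap is
  **merged** (the microexon was absorbed into a long exon). The per-species
  **microexon rate** is #microexon / (#microexon + #merged).
- **Supermatrix construction** — per-cluster per-species consensus strings
  (tags in a cluster share one length, so they are pre-aligned) are
  concatenated, with gaps for missing clusters, into FASTA / relaxed
  PHYLIP plus a partition file for maximum-likelihood tree inference.
- **Synthetic fixtures** — seeded generators for genomes with planted
  microexon genes of known size/phase/PSI, exact spliced reads,
  fraction-specific intron retention, and mutated cross-species tag
  families. These power the test suite end to end.

## Worked example

`examples/02_model_microexons.py` builds a 10-species cluster of 108-nt
tags around a 9-nt phase-1 microexon, trains the split PWM, and scans a
genome carrying two gene copies — one copy with both flanking introns, one
with all introns lost:

```
cluster cluster1: 10 tags, microexon size 9, phase 1, 10 species
split PWM part widths: [49, 9, 50] ['flank5', 'microexon', 'flank3']
  microexon  chr1:2000-2396 (+) score 170.0 gaps [206, 82]
  merged     chr1:4396-4504 (+) score 160.1 gaps [0, 0]
microexon rate: 0.5
```

The first locus is a true microexon (both gaps are canonical introns of
206 and 82 nt); in the second the three tag parts chain with zero gaps, so
the microexon is merged into a single long exon. One of two informative
loci retains the microexon, hence a rate of 0.5 for this species — the
signature of a lineage that kept one intron-bearing gene copy and one
intronless retrocopy. The other examples cover discovery with PSI
(`01`), detained-intron statistics (`03`) and supermatrix export (`04`).

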