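# Methods

This note documents the models and conventions implemented in `mek`, the
defaults that matter, what the synthetic fixtures do and do not emulate,
and the choices made where the design was genuinely open.

## Coordinates and file formats

All internal coordinates are 0-based half-open on the forward genomic
strand; 1-based inclusive coordinates exist only at file boundaries
(GTF/GFF3, SAM, junction tables), converted once in `mek.io`. GFF3 is
accepted alongside GTF by falling back from the `transcript_id` attribute
to `Parent`. SAM text is parsed with pysam; for headerless SAM (allowed by
the reader's contract) reference names are collected from the alignment
lines and a placeholder header is synthesized, since pysam cannot iterate
a SAM stream without one. "Uniquely mapped" means `NH == 1` when the tag
is present, else `MAPQ >= 20`; this generalizes aligner-specific
uniqueness conventions.

## Spanning reads and junction counting

A microexon-spanning read is an `M,N,M,N,M` run in a normalized CIGAR
(`=`/`X` folded into `M`, adjacent `M` merged): middle match of 1–15 nt
(the microexon), intron gaps within [20, 20000] nt, and outer anchors of
at least 6 nt. Anchors are whole `M` blocks; an insertion or deletion
interrupting a block ends it, which conservatively disqualifies reads that
are not cleanly split into exonic parts. Reads with more than five parts
are scanned for every embedded qualifying window. Paired-end mates are
independent observations.

Junction counting credits each `N` gap of a unique read provided the read
aligns ≥ 6 matched nt on each side of that junction, **cumulatively
across further junctions**. The cumulative rule matters: next to a 1–5 nt
microexon the adjoining match block is the microexon itself, and a
block-local threshold could never count the flanking junctions of the
smallest microexons — the class of event the toolkit exists to find. The
same logic (with the 4-nt overhang) applies to the spliced reads `e` and
`o` in the retention statistics. Intron strand and motif are read off the
genomic dinucleotides (GT/GC..AG forward; CT..AC/CT..GC implying GT-AG /
GC-AG on the minus strand).

## Calling and PSI

Candidate microexons are the 1–15 nt genomic gaps between two canonical
introns on one chromosome and strand. When several introns compete for
one side of the gap, the intron with the highest mean junction count
across all samples wins (ties: shorter intron, then leftmost). The ≥ 5
read support threshold applies to both flanking introns within a single
sample. PSI is the standard event-level estimator `I / (I + E)`: `I`
averages the two inclusion junctions' summed-over-samples counts (the two
junctions measure the same molecules, so averaging rather than summing
keeps `I` on the same per-molecule scale as `E`), and `E` is the count of
the canonical junction joining the two flanking exons directly. Samples
are pooled; the calling threshold remains per-sample.

## Intron retention and detained introns

`PIR = 100 (i1 + i2) / (i1 + i2 + 2e + 2o)`, missing when
`i1 + i2 + e + o < 10`. The doubling of `e` and `o` reflects that a
retained intron exposes two countable boundaries per molecule while a
spliced molecule yields one junction read class. "Total junction reads"
in the missing-data rule counts each read once. The unspliced ratio is
PIR/100. Detained-intron classification uses replicate means: introns
with mean cytoplasmic ratio ≥ 0.2 are excluded as not constitutively
spliced; otherwise mean chromatin-bound ratio > 0.1 marks a detained
(post-transcriptionally spliced) intron.

ISE windows scan the intron interior (10 nt trimmed at each end to avoid
splice-site signals): U(T)-rich means some 20-nt window with strictly
more than 80% T; G-rich, some 10-nt window with strictly more than 80% G.
Enrichment between microexon-flanking and control introns is a 2×2
Pearson chi-squared without continuity correction; degenerate tables
return a missing p-value.

## Microexon-tags and clustering

The tag is a 108-nt coding window centered on the microexon in CDS
coordinates. The window start is placed on a codon boundary: the left
flank length is the value congruent to the microexon's phase (mod 3)
nearest (108 − size)/2, ties resolved downward so the extra nucleotide
goes 3′. Windows are truncated in frame at the ORF start and at the last
codon before the stop, so every tag translates without stop codons. The
longest ATG-initiated ORF per transcript is used (ties: 5′-most); tag
extraction requires an ORF of ≥ 30 nt. Phase is the number of CDS
nucleotides 5′ of the microexon, mod 3 — validated against the canonical
AP2-domain example, where a 9-nt phase-1 microexon plus one upstream and
two downstream nucleotides encodes V-Y-L-G.

Tags are grouped by (size, phase) and clustered on global pairwise
peptide alignment scores under BLOSUM62 with gap open −10 and extension
−0.5 (the aligner-family default; only the substitution matrix is
prescribed by the method). Scores become distances `d = s_max − s`;
complete-linkage agglomeration cut at `s_max − 50` guarantees the strict
reading of the score-50 cutoff: *every* within-cluster pair scores ≥ 50.
Clusters need ≥ 3 distinct species. Tag order is canonicalized before
clustering, making the result order-independent. Homologous coding
fragments offered as extra PWM training data are cleaned by dropping
in-frame stops and fragments shorter than the cluster tag length,
trimming longer ones, and deduplicating. A microexon's peptide is
assigned to a protein motif if its residues lie within the motif interval
extended by 5 aa on each side; the smallest E-value wins.

## Split-PWM scanning

Column probabilities use pseudocount α = 0.25:
`p_b = (n_b + α) / (N + 4α)`; scores are base-2 log-odds against a
uniform 0.25 background. The matrix is split at the cluster's modal exon
boundaries (the microexon part is exactly delimited by two boundaries).
Each part keeps windows scoring at least
`min + 0.8 × (max − min)` of its achievable log-odds range — the
conventional default of the PWM-matching function family, exposed as
`min_score_frac`. Part hits are chained 5′→3′ with gaps of exactly 0
(intron absent) or 20 bp–10 kb (intron present) that must begin GT or GC
and end AG on the scanned strand; both strands are scanned and minus-hit
coordinates mapped back to the forward strand.

A full chain is classified **microexon** when both gaps flanking the
microexon part are introns, **merged** when either is zero. Chains
missing one terminal flank part are reported as **partial** diagnostics
and excluded from rates. Overlapping full chains are resolved by
weighted-interval scheduling — the non-overlapping set with maximal total
score — rather than greedily by single-chain score: with tandem gene
copies (the typical configuration behind 0.5 microexon rates) a chimeric
chain linking part hits of two adjacent copies through a ≤ 10 kb "intron"
can outscore either single-copy chain, and greedy selection would then
suppress both true loci. Partial chains are placed afterwards, only in
regions no full chain claimed. The per-species microexon rate for a
cluster is #microexon / (#microexon + #merged), NA with no informative
hits.

## Supermatrix

Per cluster and species, the consensus is the per-site majority base over
that species' tags (ties broken A<C<G<T; N ignored, an all-N site yields
N). Blocks are concatenated in ascending cluster-id order; species
missing a cluster receive `-` across the block. Output formats are FASTA,
relaxed PHYLIP and a per-block partition file. Tree inference itself is
out of scope: the matrix is the hand-off point to external ML software.
Both microexon and merged loci contribute tags, since merged copies still
carry the homologous coding sequence (an option restricts to
microexon-classified loci).

## Synthetic fixtures

`generate_genome` plants one microexon per gene inside an odd number of
coding exons (default 5) with canonical GT..AG introns, a single
ATG…stop ORF spanning all exons, and the microexon at a requested phase.
Defaults describe a typical plant setting: microexon sizes 1–15 weighted
3× toward 9 nt (the most abundant flowering-plant length), phase weights
16:21:8 for phases 0:1:2 (the composition observed across conserved
clusters), intron lengths 80–400 nt, exons 90–200 nt, background GC 0.36,
read length 100, depth 30×. `simulate_reads` samples (molecule, position)
pairs uniformly over transcribed bases — classes weighted by abundance ×
length, as in real RNA-seq — over the inclusion isoform (weight PSI), the
skipping isoform, and retention variants of the microexon-flanking
introns at per-fraction rates; CIGARs are computed exactly from the
isoform layout and reads are error-free by default (an optional uniform
substitution rate exists). Under this sampling the boundary-read count
among informative reads for a retained intron is Binomial with success
probability 2r/(1+r) at retention fraction r, which the tests use as the
exact convergence oracle. `mutate_homologs` derives cross-species tag
families by synonymous-biased codon mutation that never creates stops and
preserves frame, size, phase and boundaries.

What the fixtures deliberately do not emulate: sequencing error profiles
and quality strings, fragment-length and expression distributions,
multi-mapping, paralogy beyond the explicit two-copy constructions, and
alignment artifacts. Passing tests therefore demonstrate the correctness
of the toolkit's logic on ideal alignments, not robustness to mapper
noise — the alignments themselves are an input to this toolkit.

## Test problem sizes

The suite runs on desk-scale fixtures chosen to keep the full run within
seconds while still exercising every code path: 10,000+ reads for the
spanning-read oracle, 50 genes for recall, 100 single-gene replicates for
PSI calibration, a 10-species cluster for scan recovery, and 1000 random
introns for the window-scan oracle. The species-scale analyses that
motivated the methods (hundreds of RNA-seq samples, full genomes, dozens
of conserved clusters) are out of scope here; the acceptance script
reports the desk-scale worked example only.

## Known limitations

- Candidate generation pairs introns; microexons expressed only in
  contexts without junction reads on both sides (e.g. extreme 5'/3' bias)
  are invisible, as are microexons with non-canonical splice sites.
- PWM parts shorter than ~3 nt carry almost no information on their own;
  such loci are recovered only through their flanking parts, and a
  mutation in a 1–2 nt microexon can drop a true locus below threshold.
- The PIR denominator convention for the missing-data rule (each read
  counted once) is one of two defensible readings; it is exposed as the
  constant `MIN_JUNCTION_READS` rather than hidden.
- Supermatrix consensus ignores within-species paralog structure beyond
  majority voting.
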