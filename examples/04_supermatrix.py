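"""Build a phylogenomic supermatrix from microexon-tag clusters.

Derives two tag families of different microexon size from seeded genes,
takes per-species per-cluster consensus strings (tags in a cluster share a
length, so they are already aligned), and concatenates them; species
missing a cluster are padded with gaps.
"""

from mek import (
    FixtureSpec,
    build_supermatrix,
    consensus_string,
    extract_microexon_tag,
    generate_genome,
    mutate_homologs,
    orf_from_transcript,
)

consensus = {}
for cid, (seed, size) in {"c01": (3, 9), "c02": (5, 12)}.items():
    spec = FixtureSpec(seed=seed, n_genes=1, me_size_weights={size: 1.0})
    genome, models, truth = generate_genome(spec)
    orf = orf_from_transcript(models[0], genome)
    row = truth.iloc[0]
    tag = extract_microexon_tag(orf, (row.me_start, row.me_end), species="sp00")
    n_species = 6 if cid == "c01" else 4  # cluster 2 misses two species
    family = mutate_homologs(tag, n_species, rate=0.08, seed=seed + 1)
    consensus[cid] = {
        t.species: consensus_string([t.dna]) for t in family
    }

matrix = build_supermatrix(consensus)
print(f"{len(matrix.species)} species x {matrix.width} sites "
      f"(blocks: {dict(zip(matrix.cluster_ids, matrix.block_widths))})")
for sp in matrix.species:
    row = matrix.rows[sp]
    print(f"{sp:6s} {row[:30]}...{row[-12:]}")
# Species sp05/sp06 lack cluster c02: their final block is all '-', exactly
# how missing loci enter a concatenated maximum-likelihood analysis.
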