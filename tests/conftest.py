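"""Shared fixtures: small seeded genomes, reads, and tag families."""

from __future__ import annotations

import pytest

from mek import (
    FixtureSpec,
    cluster_tags,
    extract_microexon_tag,
    generate_genome,
    mutate_homologs,
    orf_from_transcript,
)


def write_sam(tmp_path, text, name="reads.sam"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


@pytest.fixture(scope="session")
def small_fixture():
    """10 genes, PSI 1, modest depth: genome, models, truth."""
    spec = FixtureSpec(seed=11, n_genes=10, depth=20)
    genome, models, truth = generate_genome(spec)
    return spec, genome, models, truth


@pytest.fixture(scope="session")
def tag_family():
    """A 10-species family of 9-nt phase-1 tags derived from one gene."""
    spec = FixtureSpec(
        seed=3, n_genes=1, me_size_weights={9: 1.0}, me_phase_weights={1: 1.0}
    )
    genome, models, truth = generate_genome(spec)
    orf = orf_from_transcript(models[0], genome)
    row = truth.iloc[0]
    tag = extract_microexon_tag(
        orf, (row.me_start, row.me_end), species="sp00", gene_id=models[0].gene_id
    )
    family = mutate_homologs(tag, 10, rate=0.1, seed=7)
    return tag, family


@pytest.fixture(scope="session")
def tag_cluster(tag_family):
    _, family = tag_family
    clusters = cluster_tags(family)
    assert len(clusters) == 1
    return clusters[0]
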