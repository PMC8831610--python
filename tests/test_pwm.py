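"""PWM construction, splitting, and split-PWM genome scanning."""

import numpy as np
import pytest

from mek import (
    Genome,
    GenomeSequence,
    build_pwm,
    scan_and_assemble,
    split_pwm,
    summarize_rates,
)
from mek.pwm import build_cluster_model
from mek.simulate import build_scan_fixture, embed_tag_locus, random_dna


class TestBuildPwm:
    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["AA", "AA", "AC", "AG"])
        # column 0: A appears 4/4 -> (4 + 0.25) / (4 + 1) = 0.85
        assert pwm.probs[0, 0] == pytest.approx(0.85)
        # column 1: A 2, C 1, G 1 -> (2 + .25)/5, (1 + .25)/5
        assert pwm.probs[0, 1] == pytest.approx(0.45)
        assert pwm.probs[1, 1] == pytest.approx(0.25)

    def test_columns_sum_to_one(self):
        pwm = build_pwm(["ACGT", "TGCA", "AAAA"])
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)

    def test_uniform_column_logodds_zero(self):
        pwm = build_pwm(["A", "C", "G", "T"])
        assert np.allclose(pwm.logodds[:, 0], 0.0)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT"])

    def test_n_sequences_dropped(self):
        pwm = build_pwm(["ACGT", "ACGT", "ANGT"])
        assert pwm.probs[0, 0] == pytest.approx((2 + 0.25) / 3)


class TestSplitPwm:
    def test_three_parts(self):
        pwm = build_pwm(["A" * 108, "C" * 108])
        spwm = split_pwm(pwm, [50, 59], me_offset=50, me_size=9)
        assert [p.length for p in spwm.parts] == [50, 9, 49]
        assert spwm.roles == ["flank5", "microexon", "flank3"]
        assert spwm.me_index == 1

    def test_five_parts(self):
        pwm = build_pwm(["A" * 108, "C" * 108])
        spwm = split_pwm(pwm, [20, 50, 59, 90], me_offset=50, me_size=9)
        assert len(spwm.parts) == 5
        assert spwm.roles == ["flank5", "flank5", "microexon", "flank3", "flank3"]

    def test_boundary_at_zero_rejected(self):
        pwm = build_pwm(["A" * 108, "C" * 108])
        with pytest.raises(ValueError):
            split_pwm(pwm, [0, 50, 59], me_offset=50, me_size=9)

    def test_microexon_must_be_delimited(self):
        pwm = build_pwm(["A" * 108, "C" * 108])
        with pytest.raises(ValueError):
            split_pwm(pwm, [40, 60], me_offset=50, me_size=9)


@pytest.fixture(scope="module")
def model_and_family(tag_cluster_module):
    cluster, family = tag_cluster_module
    return build_cluster_model(cluster), family


@pytest.fixture(scope="module")
def tag_cluster_module():
    from mek import (
        FixtureSpec,
        cluster_tags,
        extract_microexon_tag,
        generate_genome,
        mutate_homologs,
        orf_from_transcript,
    )

    spec = FixtureSpec(
        seed=3, n_genes=1, me_size_weights={9: 1.0}, me_phase_weights={1: 1.0}
    )
    genome, models, truth = generate_genome(spec)
    orf = orf_from_transcript(models[0], genome)
    row = truth.iloc[0]
    tag = extract_microexon_tag(
        orf, (row.me_start, row.me_end), species="sp00", gene_id="g"
    )
    family = mutate_homologs(tag, 10, rate=0.1, seed=7)
    return cluster_tags(family)[0], family


class TestScan:
    def test_training_locus_recovered_with_introns(self, model_and_family):
        spwm, family = model_and_family
        genomes, truth = build_scan_fixture(family, seed=21)
        tag = family[0]
        hits = scan_and_assemble(genomes[tag.species], spwm)
        me_hits = [h for h in hits if h.classification == "microexon"]
        assert len(me_hits) == 1
        row = truth[truth.species == tag.species].iloc[0]
        me_iv = me_hits[0].part_intervals[spwm.me_index]
        assert me_iv == (row.me_start, row.me_end)
        assert me_iv[1] - me_iv[0] == spwm.me_size

    def test_intronless_locus_classified_merged(self, model_and_family):
        spwm, family = model_and_family
        genomes, _ = build_scan_fixture(family[:1], seed=22, merged=[True])
        hits = scan_and_assemble(genomes[family[0].species], spwm)
        assert any(h.classification == "merged" for h in hits)
        assert not any(h.classification == "microexon" for h in hits)

    def test_intron_of_19nt_rejected(self, model_and_family):
        spwm, family = model_and_family
        tag = family[0]
        rng = np.random.default_rng(5)
        locus, _ = embed_tag_locus(tag, rng, intron_len_range=(19, 20))
        # force both introns to 19 nt
        rng = np.random.default_rng(5)
        parts = []
        cuts = [0] + sorted(tag.exon_boundary_offsets) + [len(tag.dna)]
        for s, e in zip(cuts, cuts[1:]):
            parts.append(tag.dna[s:e])
            if e < len(tag.dna):
                parts.append("GT" + "C" * 15 + "AG")  # 19-nt intron
        seq = random_dna(rng, 500) + "".join(parts) + random_dna(rng, 500)
        g = Genome.from_sequences([GenomeSequence("c", seq)])
        hits = scan_and_assemble(g, spwm)
        assert not any(h.classification == "microexon" for h in hits)

    def test_noncanonical_gap_rejected(self, model_and_family):
        spwm, family = model_and_family
        tag = family[0]
        rng = np.random.default_rng(6)
        parts = []
        cuts = [0] + sorted(tag.exon_boundary_offsets) + [len(tag.dna)]
        for s, e in zip(cuts, cuts[1:]):
            parts.append(tag.dna[s:e])
            if e < len(tag.dna):
                parts.append("AT" + "C" * 96 + "AG")  # AT donor: not canonical
        seq = random_dna(rng, 500) + "".join(parts) + random_dna(rng, 500)
        g = Genome.from_sequences([GenomeSequence("c", seq)])
        hits = scan_and_assemble(g, spwm)
        assert not any(h.classification == "microexon" for h in hits)

    def test_minus_strand_mirror(self, model_and_family):
        from mek import revcomp_fixture

        spwm, family = model_and_family
        genomes, _ = build_scan_fixture(family[:1], seed=23)
        g = genomes[family[0].species]
        fwd = scan_and_assemble(g, spwm)
        rev = scan_and_assemble(revcomp_fixture(g), spwm)
        L = len(list(g.values())[0])
        mirrored = sorted(
            ((L - e, L - s), h.classification) for h in rev for (s, e) in [h.span]
        )
        original = sorted((h.span, h.classification) for h in fwd)
        assert mirrored == original
        assert {h.strand for h in fwd} == {"+"}
        assert {h.strand for h in rev} == {"-"}

    def test_score_threshold_monotonicity(self, model_and_family):
        spwm, family = model_and_family
        genomes, _ = build_scan_fixture(family[:3], seed=24)
        g = genomes[family[0].species]
        strict = scan_and_assemble(g, spwm, min_score_frac=0.85)
        loose = scan_and_assemble(g, spwm, min_score_frac=0.75)
        strict_spans = {(h.chrom, h.span, h.strand) for h in strict}
        loose_spans = {(h.chrom, h.span, h.strand) for h in loose}
        assert strict_spans <= loose_spans

    def test_frame_preserved_across_gaps(self, model_and_family):
        spwm, family = model_and_family
        genomes, _ = build_scan_fixture(family, seed=25)
        for tag in family:
            for h in scan_and_assemble(genomes[tag.species], spwm):
                if h.classification == "partial":
                    continue
                widths = [e - s for s, e in h.part_intervals]
                assert widths[spwm.me_index] == spwm.me_size
                assert sum(widths) == spwm.tag_len


class TestRates:
    def test_half(self):
        from mek.pwm import ScanHit

        def hit(cls):
            return ScanHit("c", "+", [(0, 10)], [0], [], [], 1.0, cls)

        rates = summarize_rates({"c1": {"spA": [hit("microexon"), hit("merged")]}})
        assert rates.loc["c1", "spA"] == pytest.approx(0.5)

    def test_all_microexon_and_na(self):
        from mek.pwm import ScanHit

        def hit(cls):
            return ScanHit("c", "+", [(0, 10)], [0], [], [], 1.0, cls)

        rates = summarize_rates(
            {
                "c1": {"spA": [hit("microexon")] * 3, "spB": []},
                "c2": {"spA": [hit("partial")]},
            }
        )
        assert rates.loc["c1", "spA"] == 1.0
        assert np.isnan(rates.loc["c1", "spB"])
        assert np.isnan(rates.loc["c2", "spA"])
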