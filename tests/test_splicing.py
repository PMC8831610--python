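"""Intron retention statistics and ISE window scans."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from mek import (
    AlignmentRecord,
    classify_detained,
    compute_pir,
    intron_boundary_counts,
    motif_enrichment,
    motif_window_scan,
)
from mek.spanning import parse_cigar

INTRON = (1000, 1100)


def rec(pos, cigar):
    return AlignmentRecord("r", "c1", pos, 255, parse_cigar(cigar), 1)


class TestBoundaryCounts:
    def test_continuous_read_over_5p_boundary(self):
        i1, i2, e, o = intron_boundary_counts([rec(990, "20M")], "c1", INTRON)
        assert (i1, i2, e, o) == (1, 0, 0, 0)

    def test_three_nt_overhang_not_counted(self):
        i1, i2, e, o = intron_boundary_counts([rec(997, "7M")], "c1", INTRON)
        assert (i1, i2, e, o) == (0, 0, 0, 0)

    def test_exact_gap_counts_e_other_gap_counts_o(self):
        reads = [
            rec(980, "20M100N20M"),  # gap == intron
            rec(980, "20M150N20M"),  # overlapping, different gap
        ]
        i1, i2, e, o = intron_boundary_counts(reads, "c1", INTRON)
        assert (e, o) == (1, 1)

    def test_3p_boundary_counts_i2(self):
        i1, i2, e, o = intron_boundary_counts([rec(1090, "20M")], "c1", INTRON)
        assert (i1, i2) == (0, 1)

    def test_minus_strand_swaps_boundaries(self):
        i1, i2, e, o = intron_boundary_counts([rec(990, "20M")], "c1", INTRON, strand="-")
        assert (i1, i2) == (0, 1)


class TestComputePir:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 5, 20, 0), 20.0),
            ((0, 0, 30, 0), 0.0),
            ((10, 10, 0, 0), 100.0),
            ((3, 3, 2, 2), 100 * 6 / (6 + 4 + 4)),
        ],
    )
    def test_closed_form(self, counts, expected):
        assert compute_pir(*counts) == pytest.approx(expected)

    def test_below_ten_junction_reads_missing(self):
        assert compute_pir(2, 1, 3, 0) is None
        assert compute_pir(3, 2, 3, 2) is not None  # total exactly 10: defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_pir(-1, 0, 10, 0)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, i1, i2, e, o):
        pir = compute_pir(i1, i2, e, o)
        if pir is not None:
            assert 0.0 <= pir <= 100.0
            bigger = compute_pir(i1 + 5, i2, e, o)
            assert bigger >= pir


class TestClassifyDetained:
    def test_detained(self):
        assert classify_detained([0.25, 0.2], [0.02, 0.01]) == "detained_PTS"

    def test_constitutive(self):
        assert classify_detained([0.05], [0.01]) == "constitutive_CTS"

    def test_excluded_on_cyto(self):
        assert classify_detained([0.5], [0.30]) == "excluded"

    def test_cb_boundary_strict(self):
        assert classify_detained([0.1], [0.0]) == "constitutive_CTS"


def brute_force_windows(seq, flank=10, t_window=20, g_window=10, frac=0.8):
    interior = seq[flank : len(seq) - flank]
    t = any(
        interior[i : i + t_window].count("T") > frac * t_window
        for i in range(len(interior) - t_window + 1)
    )
    g = any(
        interior[i : i + g_window].count("G") > frac * g_window
        for i in range(len(interior) - g_window + 1)
    )
    return t, g


class TestMotifWindows:
    def test_17_of_20_t_is_rich(self):
        core = "T" * 17 + "AAA"
        seq = "G" * 10 + core + "C" * 20 + "G" * 10
        res = motif_window_scan(seq)
        assert res.has_t_rich

    def test_exactly_80_percent_not_rich(self):
        core = ("T" * 16 + "AAAC") * 3  # every 20-window has <= 16 T
        seq = "C" * 10 + core + "C" * 10
        res = motif_window_scan(seq)
        assert not res.has_t_rich

    def test_nine_of_ten_g_is_rich(self):
        seq = "C" * 10 + "GGGGGGGGGC" + "A" * 25 + "C" * 10
        assert motif_window_scan(seq).has_g_rich

    def test_flanks_excluded_from_interior(self):
        # the T-run sits inside the first 10 nt: must not count
        seq = "T" * 10 + "ACACA" * 9 + "A" * 10
        assert not motif_window_scan(seq).has_t_rich

    def test_short_intron_all_false(self):
        assert motif_window_scan("T" * 40) == motif_window_scan("A" * 30)

    def test_matches_brute_force_oracle_on_random_introns(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(41, 200))
            # skewed composition so rich windows actually occur
            p = rng.dirichlet([1, 1, 2, 4])
            seq = "".join(bases[rng.choice(4, size=n, p=p)])
            res = motif_window_scan(seq)
            t, g = brute_force_windows(seq)
            assert (res.has_t_rich, res.has_g_rich) == (t, g)


class TestEnrichment:
    def test_identical_proportions(self):
        stat, p = motif_enrichment([True, False], [True, False])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_pearson_formula(self):
        me = [True] * 141 + [False] * 859
        ctrl = [True] * 93 + [False] * 907
        stat, p = motif_enrichment(me, ctrl)
        table = np.array([[141, 93], [859, 907]])
        expected = chi2_contingency(table.T, correction=False)
        # hand-computed Pearson statistic
        n = table.sum()
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        exp = rows @ cols / n
        hand = (((table - exp) ** 2) / exp).sum()
        assert stat == pytest.approx(hand)
        assert stat == pytest.approx(expected.statistic)

    def test_degenerate_table(self):
        stat, p = motif_enrichment([True, True], [True, True])
        assert p is None
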