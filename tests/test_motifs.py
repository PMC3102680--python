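from fractions import Fraction
from math import comb

import numpy as np
import pytest

from phosphopath import motifs
from phosphopath.io_formats import load_ras_concurrence_table
from phosphopath.motifs import (
    EnrichmentConfig,
    MotifClass,
    MotifPattern,
    classify_window,
    extract_window,
    homogeneity_test,
    matching_classes,
    motifx_enrich,
    subset_frequencies,
    window_from_marked_peptide,
)


def exact_binomial_tail(k, n, p0):
    """Independent oracle: P(X >= k) by exact rational summation of the pmf."""
    p = Fraction(p0).limit_denominator(10**9)
    q = 1 - p
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * p**i * q ** (n - i)
    return float(total)


class TestWindows:
    def test_terminal_padding(self):
        assert extract_window("MKSPR", 3) == "____MKSPR____"

    def test_interior_site_no_padding(self):
        seq = "ABCDEFSHIJKLMNOPQRST".replace("B", "A")  # 20-mer, S at 7
        assert extract_window(seq, 7) == seq[0:13]
        assert "_" not in extract_window(seq, 7)

    def test_non_phospho_center_rejected(self):
        with pytest.raises(ValueError, match="not S/T/Y"):
            extract_window("MKAPR", 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_window("MKSPR", 9)

    def test_window_from_marked_peptide(self):
        assert window_from_marked_peptide("LSPpSPTSQR") == "___LSPSPTSQR_"


class TestClassification:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AAAAAATPPVSPA", MotifClass.PROLINE_DIRECTED),  # P at +1
            ("AAARAASAAAAAA", MotifClass.BASOPHILIC),        # R at −3
            ("AAARAASPAAAAA", MotifClass.PROLINE_DIRECTED),  # dual motif: precedence
            ("AAAAAASDAAAAA", MotifClass.ACIDOPHILIC),       # D at +1
            ("AAAAAASAAEAAA", MotifClass.ACIDOPHILIC),       # E at +3
            ("AAAAAASAAAAAA", MotifClass.OTHER),
        ],
    )
    def test_consensus_rules_and_precedence(self, window, expected):
        assert classify_window(window) is expected

    def test_dual_motifs_all_reported(self):
        assert matching_classes("AAARAASPAAAAA") == [
            MotifClass.PROLINE_DIRECTED,
            MotifClass.BASOPHILIC,
        ]

    def test_published_site_contexts_are_mostly_proline_directed(self):
        """Sites of the packaged Ras-regulation table, classified from their
        peptide contexts: the proline-directed subset is modal."""
        rt = load_ras_concurrence_table()
        classes = [
            classify_window(window_from_marked_peptide(p))
            for p in rt.meta["peptide_sequence"]
        ]
        freq = subset_frequencies(classes)
        assert freq.modal_class is MotifClass.PROLINE_DIRECTED
        assert freq.counts[MotifClass.PROLINE_DIRECTED] >= 10

    def test_generated_sites_match_ground_truth_class(self, small_dataset):
        for pid, row in small_dataset.quant.meta.iterrows():
            if row["is_standard"]:
                continue
            acc = row["protein_accession"]
            pos = int(row["sites"][1:])
            window = extract_window(small_dataset.sequences[acc], pos)
            assert classify_window(window) is small_dataset.truth.site_class[pid]


class TestBinomialTail:
    def test_agrees_with_exact_summation(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 300))
            k = int(rng.integers(1, n + 1))
            p0 = float(rng.uniform(0.01, 0.6))
            ours = motifs.binomial_tail(k, n, p0)
            exact = exact_binomial_tail(k, n, p0)
            assert ours == pytest.approx(exact, rel=1e-9)


def constant_window(residues_at: dict[int, str], center="S") -> str:
    cells = ["A"] * 13
    cells[6] = center
    for off, res in residues_at.items():
        cells[6 + off] = res
    return "".join(cells)


def random_windows(rng, n, p_plus1_p=0.0, p_minus3_r=0.0):
    """Windows with alanine backdrop, G filler, and controlled motif rates."""
    out = []
    for _ in range(n):
        cells = list(rng.choice(list("AGLVNQ"), size=13))
        cells[6] = "S"
        u = rng.random()
        if u < p_plus1_p:
            cells[7] = "P"
        elif u < p_plus1_p + p_minus3_r:
            cells[3] = "R"
        out.append("".join(cells))
    return out


class TestMotifxEnrichment:
    def test_pure_foreground_recovers_single_pattern(self, rng):
        bg = random_windows(rng, 2000, p_plus1_p=0.10)
        fg = random_windows(rng, 200, p_plus1_p=1.0)
        res = motifx_enrich(fg, bg)
        assert len(res) == 1
        assert res[0].pattern.constraints == ((1, frozenset("P")),)
        # k = n = 200 at background rate ~0.1 → p ≈ 0.1^200, far below threshold
        assert res[0].p_value < 1e-150

    def test_background_distributed_foreground_yields_nothing(self, rng):
        bg = random_windows(rng, 2000, p_plus1_p=0.10, p_minus3_r=0.10)
        fg = random_windows(rng, 150, p_plus1_p=0.10, p_minus3_r=0.10)
        assert motifx_enrich(fg, bg) == []

    def test_two_block_foreground_returns_both_in_order(self, rng):
        bg = random_windows(rng, 3000, p_plus1_p=0.10, p_minus3_r=0.10)
        fg = random_windows(rng, 120, p_plus1_p=1.0) + random_windows(rng, 80, p_minus3_r=1.0)
        res = motifx_enrich(fg, bg)
        patterns = [r.pattern.constraints for r in res]
        assert ((1, frozenset("P")),) in patterns
        assert ((-3, frozenset("R")),) in patterns
        # larger block fixed first (more significant at equal background rate)
        assert patterns[0] == ((1, frozenset("P")),)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            motifx_enrich([], [constant_window({})])

    def test_min_occurrence_gate(self, rng):
        bg = random_windows(rng, 1000, p_plus1_p=0.10)
        fg = [constant_window({1: "P"})] * 10  # significant but too few
        assert motifx_enrich(fg, bg, EnrichmentConfig(min_occurrences=20)) == []


class TestSubsetFrequencies:
    def test_counts(self):
        freq = subset_frequencies(
            [
                MotifClass.PROLINE_DIRECTED,
                MotifClass.PROLINE_DIRECTED,
                MotifClass.BASOPHILIC,
                MotifClass.OTHER,
            ]
        )
        assert freq.as_vector().tolist() == [2, 1, 0, 1]
        assert sum(freq.proportions.values()) == pytest.approx(1.0)

    def test_single_class(self):
        freq = subset_frequencies([MotifClass.PROLINE_DIRECTED] * 5)
        assert freq.proportions[MotifClass.PROLINE_DIRECTED] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subset_frequencies([])


class TestHomogeneity:
    def test_identical_rows(self):
        stat, dof, p = homogeneity_test([30, 10, 5, 5], [30, 10, 5, 5])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_completely_disjoint(self):
        stat, dof, p = homogeneity_test([50, 0], [0, 50])
        assert stat == pytest.approx(100.0)
        assert dof == 1
        assert p < 1e-4

    def test_similar_rows_not_significant(self):
        stat, dof, p = homogeneity_test([30, 10], [28, 12])
        assert dof == 1
        assert p > 0.05

    def test_matches_first_principles_chi_square(self, rng):
        """Oracle: Pearson chi-square computed directly from expected counts."""
        for _ in range(20):
            a = rng.integers(1, 60, size=4)
            b = rng.integers(1, 60, size=4)
            stat, dof, p = homogeneity_test(a, b)
            table = np.vstack([a, b]).astype(float)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            brute = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(brute, rel=1e-12)
            assert dof == 3

    def test_zero_total_category_dropped(self):
        stat, dof, p = homogeneity_test([30, 10, 0], [28, 12, 0])
        assert dof == 1

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            homogeneity_test([0, 0], [1, 2])


def test_pattern_notation_round_trip_readability():
    pat = MotifPattern.of(p1="P", m3="R")
    assert pat.notation() == "...R..*P......"[: 2 * motifs.FLANK + 1]
    assert pat.matches("AAARAASPAAAAA")
    assert not pat.matches("AAAAAASPAAAAA")
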