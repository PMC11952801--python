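import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kiclib import (
    BLOSUM62_BACKGROUND,
    OrthologAlignment,
    Phosphosite,
    classify_conserved_sites,
    classify_potentially_conserved,
    column_distribution,
    jsd_score,
    relative_entropy,
    site_window_score,
)
from kiclib.formats_io import AMINO_ACIDS

from oracles import naive_window_score

UNIFORM20 = {aa: 1 / 20 for aa in AMINO_ACIDS}


def random_distribution(rng, symbols):
    probs = rng.dirichlet(np.ones(len(symbols)))
    return dict(zip(symbols, probs))


class TestColumnDistribution:
    def test_point_mass(self):
        assert column_distribution("AAAA")["A"] == 1.0

    def test_direct_frequencies_with_gap(self):
        dist = column_distribution("AAC-")
        assert dist["A"] == 0.5 and dist["C"] == 0.25 and dist["-"] == 0.25

    def test_hand_tally_of_mixed_column(self):
        dist = column_distribution(list("STSAY-"))
        expected = {"S": 2 / 6, "T": 1 / 6, "A": 1 / 6, "Y": 1 / 6, "-": 1 / 6}
        for sym, freq in expected.items():
            assert dist[sym] == pytest.approx(freq)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="'Z'"):
            column_distribution("AZ")


class TestRelativeEntropy:
    def test_identical_distributions_give_zero(self):
        assert relative_entropy(UNIFORM20, UNIFORM20) == pytest.approx(0.0)

    def test_point_mass_against_uniform(self):
        assert relative_entropy({"A": 1.0}, UNIFORM20) == pytest.approx(
            math.log2(20), abs=1e-9
        )

    def test_two_term_hand_computation(self):
        p = {"A": 0.5, "C": 0.5}
        q = {"A": 0.25, "C": 0.75}
        expected = 0.5 * math.log2(2) + 0.5 * math.log2(2 / 3)
        assert relative_entropy(p, q) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.2075, abs=5e-5)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_entropy({"A": 1.0}, {"C": 1.0})

    @given(st.integers(0, 10_000))
    def test_nonnegative_over_random_distributions(self, seed):
        rng = np.random.default_rng(seed)
        symbols = list(AMINO_ACIDS)
        p = random_distribution(rng, symbols)
        q = random_distribution(rng, symbols)
        assert relative_entropy(p, q) >= 0.0
        assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-12)


class TestJsdScore:
    def test_zero_for_identical(self):
        assert jsd_score(UNIFORM20, UNIFORM20) == pytest.approx(0.0)

    def test_disjoint_point_masses_are_maximal(self):
        assert jsd_score({"A": 1.0}, {"C": 1.0}) == pytest.approx(1.0)

    def test_point_mass_against_uniform(self):
        assert jsd_score({"A": 1.0}, UNIFORM20) == pytest.approx(0.855, abs=5e-4)

    @given(st.integers(0, 10_000))
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        symbols = list(AMINO_ACIDS + "-")
        p = random_distribution(rng, symbols)
        q = random_distribution(rng, symbols)
        score = jsd_score(p, q)
        assert 0.0 <= score <= 1.0
        assert score == pytest.approx(jsd_score(q, p), abs=1e-12)


def _uniform_rows(columns):
    """Build alignment rows from a list of per-column strings."""
    n = len(columns[0])
    return ["".join(col[i] for col in columns) for i in range(n)]


class TestSiteWindowScore:
    def test_background_matching_columns_score_zero(self):
        # every column is AACC; against a {A:1/2, C:1/2} background PM = 0
        rows = ["A" * 11, "A" * 11, "C" * 11, "C" * 11]
        background = {"A": 0.5, "C": 0.5}
        profile = site_window_score(
            OrthologAlignment(rows, ["s1", "s2", "s3", "s4"]),
            site_column=5,
            background=background,
        )
        assert profile.window_score == pytest.approx(0.0, abs=1e-12)
        assert profile.n == 10

    def test_identical_single_letter_columns_equal_single_pm(self):
        rows = ["W" * 11] * 3
        msa = OrthologAlignment(rows, ["s1", "s2", "s3"])
        profile = site_window_score(msa, site_column=5)
        single = jsd_score({"W": 1.0}, BLOSUM62_BACKGROUND)
        assert profile.window_score == pytest.approx(single)
        assert all(s == pytest.approx(single) for s in profile.column_scores)

    def test_site_column_is_excluded(self):
        # site column is wildly conserved W, flanks are AACC-like columns
        rows = ["AWAAA", "AWAAA", "CWCCC", "CWCCC"]
        background = {"A": 0.5, "C": 0.5}
        profile = site_window_score(
            OrthologAlignment(rows, list("abcd")), site_column=1,
            background=background, half_width=2,
        )
        assert profile.window_score == pytest.approx(0.0, abs=1e-12)
        assert 1 not in profile.window_columns

    def test_window_truncates_at_alignment_ends(self):
        rows = ["W" * 8] * 3
        profile = site_window_score(OrthologAlignment(rows, list("abc")), 1)
        # columns 0, 2..6 are in range; site column 1 excluded
        assert profile.n == 6

    def test_matches_brute_force_on_toy_msa(self, rng):
        columns = (["AAAA"] * 3 + ["WWWW", "DDDD"] + ["ASTC"]
                   + ["KKKK", "LLLL"] + ["ACAC"] * 3)
        rows = _uniform_rows(columns)
        msa = OrthologAlignment(rows, list("abcd"))
        got = site_window_score(msa, site_column=5).window_score
        expected = naive_window_score(rows, 5, dict(BLOSUM62_BACKGROUND))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_msas(self, rng):
        symbols = list(AMINO_ACIDS + "-")
        for _ in range(100):
            n = int(rng.integers(2, 7))
            length = int(rng.integers(3, 16))
            rows = [
                "".join(rng.choice(symbols, size=length)) for _ in range(n)
            ]
            site = int(rng.integers(0, length))
            try:
                got = site_window_score(
                    OrthologAlignment(rows, [f"s{i}" for i in range(n)]), site
                ).window_score
            except ValueError:
                assert length == 1
                continue
            expected = naive_window_score(rows, site, dict(BLOSUM62_BACKGROUND))
            assert got == pytest.approx(expected, abs=1e-10)


def _two_species_alignment():
    # Query (ath) and soybean rows share an alignment; T at ath:6 maps to
    # column 6; the soybean row has a gap at column 2, so its positions shift.
    rows = [
        "MKLVWSTAGY",
        "MK-VWSSAGY",
        "MKLVWSAAGY",
    ]
    return OrthologAlignment(
        rows,
        species_labels=["ath", "gma", "osa"],
        row_ids=["AT1", "GM1", "OS1"],
        query_row=0,
    )


class TestClassifyConserved:
    def test_two_species_same_column_is_conserved(self):
        msa = _two_species_alignment()
        sites = [
            Phosphosite("AT1", 7, "T", "ath"),  # column 6
            Phosphosite("GM1", 6, "S", "gma"),  # gap at col 2 shifts: col 6
        ]
        hits = classify_conserved_sites([msa], sites)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.site.protein_id == "AT1" and hit.column == 6
        assert hit.n_species == 2 and hit.species == ("ath", "gma")

    def test_single_species_not_conserved(self):
        msa = _two_species_alignment()
        hits = classify_conserved_sites([msa], [Phosphosite("AT1", 7, "T", "ath")])
        assert hits == []

    def test_acceptor_residue_may_differ_across_species(self):
        # T-phospho in ath, S-phospho in gma at the same column still counts
        msa = _two_species_alignment()
        sites = [
            Phosphosite("AT1", 7, "T", "ath"),
            Phosphosite("GM1", 6, "S", "gma"),
        ]
        assert len(classify_conserved_sites([msa], sites)) == 1

    def test_inconsistent_site_raises(self):
        msa = _two_species_alignment()
        with pytest.raises(ValueError, match="alignment has"):
            classify_conserved_sites([msa], [Phosphosite("AT1", 6, "T", "ath")])


class TestClassifyPotentiallyConserved:
    def test_orthologs_with_acceptors_are_eligible(self):
        rows = ["AAAAATAAAAA", "AAAAASAAAAA", "AAAAATAAAAA"]
        msa = OrthologAlignment(rows, ["ath", "osa", "gma"],
                                row_ids=["A", "B", "C"])
        eligible, profile = classify_potentially_conserved(
            msa, Phosphosite("A", 6, "T", "ath")
        )
        assert eligible and profile.n == 10
        assert profile.window_score > 0.5  # fully conserved flanks

    def test_non_acceptor_ortholog_blocks_eligibility(self):
        rows = ["AAAAATAAAAA", "AAAAAAAAAAA", "AAAAATAAAAA"]
        msa = OrthologAlignment(rows, ["ath", "osa", "gma"],
                                row_ids=["A", "B", "C"])
        eligible, profile = classify_potentially_conserved(
            msa, Phosphosite("A", 6, "T", "ath")
        )
        assert not eligible and profile is None

    def test_two_row_alignment_rejected(self):
        msa = OrthologAlignment(
            ["AAAAATAAAAA", "AAAAASAAAAA"], ["ath", "osa"], row_ids=["A", "B"]
        )
        with pytest.raises(ValueError, match="N >= 3"):
            classify_potentially_conserved(msa, Phosphosite("A", 6, "T", "ath"))


class TestAlignmentInvariants:
    def test_residue_column_maps_are_mutually_inverse(self):
        msa = _two_species_alignment()
        for row in range(msa.n_rows):
            ungapped = msa.ungapped(row)
            for pos in range(1, len(ungapped) + 1):
                col = msa.residue_to_column(row, pos)
                assert msa.column_to_residue(row, col) == pos

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            OrthologAlignment(["AAA", "AA"], ["a", "b"])
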