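"""Heterosis ratios, letter displays, dominance, clustering, chlorophyll."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteroseq import (
    DataError,
    chlorophyll_per_mg_fw,
    cluster_profiles,
    dominance_class,
    heterosis_ratios,
    heterosis_table,
    median_center,
    mid_parent_value,
    pairwise_letter_groups,
    total_chlorophyll,
)
from heteroseq.heterosis import _ttest


class TestRatios:
    def test_mid_parent_value_is_arithmetic_mean(self):
        assert mid_parent_value(52.87, 53.59) == pytest.approx(53.23)
        assert mid_parent_value(7.0, 7.0) == 7.0
        assert mid_parent_value(0.0, 10.0) == 5.0

    @pytest.mark.parametrize(
        "p1,p2,f1,expected",
        [
            (52.87, 53.59, 68.82, (1.29, 1.28)),  # cotyledon area, day 4
            (146.48, 114.62, 179.13, (1.37, 1.22)),  # leaf area, day 14
            (10.0, 10.0, 10.0, (1.00, 1.00)),  # no heterosis
        ],
    )
    def test_published_style_ratios(self, p1, p2, f1, expected):
        assert heterosis_ratios(p1, p2, f1) == expected

    def test_nonpositive_parent_rejected(self):
        with pytest.raises(DataError):
            heterosis_ratios(0.0, 5.0, 5.0)

    def test_f1_at_best_parent_gives_bpv_ratio_one(self):
        assert heterosis_ratios(80.0, 100.0, 100.0)[1] == 1.00

    @given(
        p1=st.floats(1, 1e3), p2=st.floats(1, 1e3), f1=st.floats(0.1, 1e3)
    )
    @settings(max_examples=200, derandomize=True)
    def test_mpv_ratio_at_least_bpv_ratio(self, p1, p2, f1):
        r_mpv, r_bpv = heterosis_ratios(p1, p2, f1)
        # BPV >= MPV for any pair of parents, hence F1/MPV >= F1/BPV
        assert r_mpv >= r_bpv


def _brute_force_letter_check(samples, letters, alpha=0.05):
    """Oracle: shared-letter relation must equal non-significance."""
    for a, b in itertools.combinations(samples, 2):
        p = _ttest(samples[a], samples[b])
        share = bool(set(letters[a]) & set(letters[b]))
        assert share == (p >= alpha), (a, b, p, letters)


class TestLetterGroups:
    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        samples = {
            "F1": rng.normal(100, 1, 10),
            "P2": rng.normal(50, 1, 10),
            "P1": rng.normal(10, 1, 10),
        }
        letters = pairwise_letter_groups(samples)
        assert letters == {"F1": "a", "P2": "b", "P1": "c"}
        _brute_force_letter_check(samples, letters)

    def test_identical_distributions_share_one_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1, 30)
        samples = {"P1": base, "P2": base.copy(), "F1": base.copy()}
        letters = pairwise_letter_groups(samples)
        assert set(letters.values()) == {"a"}

    def test_chain_pattern_gets_overlapping_middle(self):
        # A vs C significant; A-B and B-C not: expect a / ab / b
        a = np.array([10.0, 10.4, 9.6, 10.2, 9.8])
        b = a - 0.35
        c = a - 0.7
        samples = {"A": a, "B": b, "C": c}
        letters = pairwise_letter_groups(samples)
        assert letters == {"A": "a", "B": "ab", "C": "b"}
        _brute_force_letter_check(samples, letters)

    def test_random_groups_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            k = rng.integers(2, 6)
            samples = {
                f"G{i}": rng.normal(rng.uniform(0, 3), 1, 8)
                for i in range(k)
            }
            letters = pairwise_letter_groups(samples)
            _brute_force_letter_check(samples, letters)

    def test_single_observation_group_rejected(self):
        with pytest.raises(DataError):
            pairwise_letter_groups({"A": [1.0], "B": [1.0, 2.0]})


class TestDominance:
    def test_overdominant_when_f1_above_both(self):
        rng = np.random.default_rng(4)
        cls = dominance_class(
            rng.normal(10, 1, 10), rng.normal(12, 1, 10), rng.normal(20, 1, 10)
        )
        assert cls == "above-both"

    def test_underdominant_when_f1_below_both(self):
        rng = np.random.default_rng(5)
        cls = dominance_class(
            rng.normal(10, 1, 10), rng.normal(12, 1, 10), rng.normal(2, 1, 10)
        )
        assert cls == "below-both"

    def test_identical_groups_within_range(self):
        x = np.array([5.0, 5.5, 4.5, 5.2])
        assert dominance_class(x, x, x) == "within-parental-range"

    def test_nonsignificant_excess_stays_within_range(self):
        # F1 mean above both parents but noise swamps the difference
        rng = np.random.default_rng(6)
        cls = dominance_class(
            rng.normal(10, 8, 5), rng.normal(10, 8, 5), rng.normal(11, 8, 5)
        )
        assert cls == "within-parental-range"


class TestChlorophyll:
    def test_linear_form(self):
        assert total_chlorophyll(0.0, 0.0) == 0.0
        assert total_chlorophyll(1.0, 0.0) == pytest.approx(17.76)
        assert total_chlorophyll(0.0, 1.0) == pytest.approx(7.34)
        assert total_chlorophyll(0.5, 0.5) == pytest.approx(12.55)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DataError):
            total_chlorophyll(-0.1, 0.2)

    def test_fresh_weight_normalisation(self):
        # 1 mL extract from 100 mg tissue: ug/mL -> ug/mg / 100
        assert chlorophyll_per_mg_fw(0.5, 0.5, 1.0, 100.0) == pytest.approx(
            0.1255
        )


class TestClustering:
    def test_three_leaf_upgma_oracle(self):
        # profiles {0}, {1}, {5}: merge (0,1) at height 1, then at
        # average distance (5 + 4) / 2 = 4.5
        mat = pd.DataFrame({"x": [0.0, 1.0, 5.0]}, index=["a", "b", "c"])
        dend, _ = cluster_profiles(mat, center=False)
        merges = dend.merges
        assert merges[0] == (frozenset({"a", "b"}), pytest.approx(1.0))
        assert merges[1][0] == frozenset({"a", "b", "c"})
        assert merges[1][1] == pytest.approx(4.5)

    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(7)
        row = rng.normal(0, 1, 6)
        mat = pd.DataFrame(
            [row, row, rng.normal(5, 1, 6)], index=["a", "b", "c"]
        )
        dend, _ = cluster_profiles(mat)
        assert dend.merges[0] == (frozenset({"a", "b"}), pytest.approx(0.0))

    def test_merge_heights_non_decreasing_and_permutation_invariant(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(
            rng.normal(0, 1, (8, 5)), index=[f"r{i}" for i in range(8)]
        )
        dend, _ = cluster_profiles(mat)
        heights = [h for _, h in dend.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        shuffled = mat.sample(frac=1, random_state=1)
        dend2, _ = cluster_profiles(shuffled)
        assert [set(m) for m, _ in dend.merges] == [
            set(m) for m, _ in dend2.merges
        ]
        assert heights == pytest.approx([h for _, h in dend2.merges])

    def test_display_matrix_rows_have_zero_median(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(3, 2, (5, 7)))
        centered = median_center(mat)
        assert centered.median(axis=1).abs().max() < 1e-12

    def test_missing_values_use_pairwise_complete_distance(self):
        mat = pd.DataFrame(
            {
                "c1": [0.0, 0.0, 10.0],
                "c2": [1.0, np.nan, 11.0],
                "c3": [2.0, 2.0, 12.0],
            },
            index=["a", "b", "c"],
        )
        dend, _ = cluster_profiles(mat)
        assert dend.merges[0][0] == frozenset({"a", "b"})

    def test_all_missing_row_rejected(self):
        mat = pd.DataFrame(
            {"c1": [1.0, np.nan], "c2": [2.0, np.nan]}, index=["a", "b"]
        )
        with pytest.raises(DataError):
            cluster_profiles(mat)

    def test_newick_export_parses_back(self):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(10)
        mat = pd.DataFrame(
            rng.normal(0, 1, (5, 4)), index=list("abcde")
        )
        dend, _ = cluster_profiles(mat)
        tree = Phylo.read(StringIO(dend.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcde")


class TestHeterosisTable:
    def test_table_reproduces_ratio_and_letters(self, default_sim):
        table = heterosis_table(default_sim.phenotypes)
        assert set(table["trait"]) == {
            "cotyledon_area_mm2", "leaf_area_mm2", "fresh_weight_mg",
        }
        row = table.set_index(["trait", "stage"]).loc[
            ("cotyledon_area_mm2", 4)
        ]
        expected_mpv, expected_bpv = heterosis_ratios(
            row["mean_p1"], row["mean_p2"], row["mean_f1"]
        )
        assert row["ratio_mpv"] == expected_mpv
        assert row["ratio_bpv"] == expected_bpv

    def test_nonfinite_values_rejected(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a", "b"],
                "line": ["P1", "P2"],
                "stage": [2, 2],
                "trait": ["t", "t"],
                "value": [1.0, np.inf],
            }
        )
        with pytest.raises(DataError):
            heterosis_table(df)
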