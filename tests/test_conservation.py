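"""Conservation scoring, binning, ΔΔG aggregation and the correlation."""

import numpy as np
import pandas as pd
import pytest

from kunitzchar.conservation import (
    DEFAULT_BINS,
    MultipleAlignment,
    TAYLOR_PROPERTIES,
    amas_score_column,
    bin_scores,
    conservation_stability_regression,
    map_positions_to_columns,
    mean_ddg_per_column,
    score_alignment,
)

RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")


def oracle_score(column):
    """Independent property-count oracle."""
    if "-" in column:
        return 0
    if len(set(column)) == 1:
        return 11
    score = 0
    for members in TAYLOR_PROPERTIES.properties.values():
        flags = [aa in members for aa in column]
        if all(flags) or not any(flags):
            score += 1
    return min(score, 10)


class TestColumnScore:
    def test_identical_column_scores_eleven(self):
        assert amas_score_column(["K", "K", "K"]) == 11

    def test_gap_annihilates(self):
        assert amas_score_column(["K", "-", "K"]) == 0

    def test_gap_exclusion_mode(self):
        assert amas_score_column(["K", "-", "K"], gap_mode="exclude") == 11

    def test_aliphatic_column_matches_oracle(self):
        col = ["I", "L", "V"]
        assert amas_score_column(col) == oracle_score(col)

    def test_random_columns_match_oracle(self, rng):
        for _ in range(500):
            col = list(rng.choice(RESIDUES, size=3))
            assert amas_score_column(col) == oracle_score(col), col

    def test_row_permutation_and_duplication_invariance(self, rng):
        col = list(rng.choice(RESIDUES, size=4))
        s = amas_score_column(col)
        assert amas_score_column(col[::-1]) == s
        assert amas_score_column(col + col) == s

    def test_adding_distinct_residue_never_increases(self, rng):
        for _ in range(100):
            col = list(rng.choice(RESIDUES, size=3))
            extra = rng.choice([r for r in RESIDUES if r not in col])
            assert amas_score_column(col + [extra]) <= amas_score_column(col)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            amas_score_column(["K", "B"])


class TestAlignmentScore:
    def test_identical_rows_all_eleven(self):
        aln = MultipleAlignment([("a", "DANSFG"), ("b", "DANSFG")])
        assert set(score_alignment(aln).scores) == {11}

    def test_inhibitor_pair_conserves_all_six_cysteines(
        self, atpi1_chain, atpi2_chain
    ):
        aln = MultipleAlignment(
            [("ATPI-I", atpi1_chain), ("ATPI-II", "--" + atpi2_chain)]
        )
        profile = score_alignment(aln)
        cys_cols = [j for j, aa in enumerate(atpi1_chain) if aa == "C"]
        assert len(cys_cols) == 6
        assert all(profile.scores[j] == 11 for j in cys_cols)

    def test_histogram_sums_to_length(self, rng):
        rows = ["".join(rng.choice(RESIDUES, size=40)) for _ in range(5)]
        aln = MultipleAlignment([(f"s{i}", r) for i, r in enumerate(rows)])
        profile = score_alignment(aln)
        assert profile.histogram().sum() == 40


class TestBins:
    def test_all_eleven_fall_in_top_bin(self):
        aln = MultipleAlignment([("a", "DANSFG"), ("b", "DANSFG")])
        counts = score_alignment(aln).bin_counts()
        assert counts[(9, 11)] == 6
        assert sum(counts.values()) == 6

    def test_random_profile_counts_equal_direct_tally(self, rng):
        aln = MultipleAlignment(
            [(f"s{i}", "".join(rng.choice(RESIDUES, size=60))) for i in range(6)]
        )
        profile = score_alignment(aln)
        assignment = bin_scores(profile)
        for i, (lo, hi) in enumerate(DEFAULT_BINS):
            direct = int(np.sum((profile.scores >= lo) & (profile.scores <= hi)))
            assert int(np.sum(assignment == i)) == direct

    def test_non_partition_bins_rejected(self):
        aln = MultipleAlignment([("a", "DA"), ("b", "DA")])
        profile = score_alignment(aln)
        with pytest.raises(ValueError):
            bin_scores(profile, [(0, 5), (4, 11)])


class TestDdgAggregation:
    def test_position_to_column_mapping_skips_gaps(self):
        assert map_positions_to_columns("A-CD") == {1: 0, 2: 2, 3: 3}

    def test_single_homolog_identity(self):
        aln = MultipleAlignment([("h1", "KDE"), ("h2", "KDE")])
        ddg = pd.DataFrame(
            {"homolog_id": ["h1"] * 3, "position": [1, 2, 3],
             "ddG_kcal_mol": [1.0, 2.0, 3.0]}
        )
        out = mean_ddg_per_column(ddg, aln)
        np.testing.assert_allclose(out["mean_ddG_kcal_mol"], [1.0, 2.0, 3.0])

    def test_known_means_recovered_across_homologs(self):
        aln = MultipleAlignment([("h1", "KD"), ("h2", "KD")])
        ddg = pd.DataFrame(
            {"homolog_id": ["h1", "h2", "h1", "h2"],
             "position": [1, 1, 2, 2],
             "ddG_kcal_mol": [1.0, 3.0, 2.0, 4.0]}
        )
        out = mean_ddg_per_column(ddg, aln)
        np.testing.assert_allclose(out["mean_ddG_kcal_mol"], [2.0, 3.0])
        assert list(out["n_obs"]) == [2, 2]

    def test_column_without_observation_flagged_missing(self):
        aln = MultipleAlignment([("h1", "AK"), ("h2", "AK")])
        ddg = pd.DataFrame(
            {"homolog_id": ["h1"], "position": [2], "ddG_kcal_mol": [1.5]}
        )
        out = mean_ddg_per_column(ddg, aln)
        assert np.isnan(out["mean_ddG_kcal_mol"][0])
        assert out["n_obs"][0] == 0

    def test_out_of_range_position_rejected(self):
        aln = MultipleAlignment([("h1", "AK"), ("h2", "AK")])
        ddg = pd.DataFrame(
            {"homolog_id": ["h1"], "position": [5], "ddG_kcal_mol": [1.0]}
        )
        with pytest.raises(ValueError):
            mean_ddg_per_column(ddg, aln)


def _profile_and_table(scores, ddg_values):
    from kunitzchar.conservation import ConservationProfile

    profile = ConservationProfile(np.asarray(scores), [("X",)] * len(scores))
    table = pd.DataFrame(
        {"column": np.arange(len(scores)),
         "mean_ddG_kcal_mol": ddg_values,
         "n_obs": np.ones(len(scores), dtype=int)}
    )
    return profile, table


class TestRegression:
    def test_exact_linear_relation_gives_unit_r(self):
        scores = [0, 2, 4, 6, 8, 10]
        profile, table = _profile_and_table(scores, 0.5 + 0.3 * np.array(scores))
        reg = conservation_stability_regression(profile, table)
        assert reg.r == pytest.approx(1.0)
        assert reg.slope == pytest.approx(0.3)
        assert reg.intercept == pytest.approx(0.5)

    def test_anticorrelated_data_negative_r(self):
        scores = [0, 2, 4, 6, 8, 10]
        profile, table = _profile_and_table(scores, 5.0 - 0.4 * np.array(scores))
        assert conservation_stability_regression(profile, table).r < 0

    def test_affine_rescaling_preserves_abs_r(self, rng):
        scores = rng.integers(0, 12, 30)
        vals = 0.3 * scores + rng.normal(0, 1, 30)
        profile, table = _profile_and_table(scores, vals)
        r1 = conservation_stability_regression(profile, table).r
        profile2, table2 = _profile_and_table(scores, -2.5 * vals + 7.0)
        r2 = conservation_stability_regression(profile2, table2).r
        assert abs(r2) == pytest.approx(abs(r1))
        assert np.sign(r2) == -np.sign(r1)

    def test_zero_variance_flagged_undefined(self):
        profile, table = _profile_and_table([5, 5, 5, 5], [1.0, 2.0, 3.0, 4.0])
        reg = conservation_stability_regression(profile, table)
        assert not reg.defined
        assert np.isnan(reg.r)
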