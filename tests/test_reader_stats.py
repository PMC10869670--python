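import itertools

import numpy as np
import pytest
from scipy import stats

from sdsa.reader_stats import (
    ReaderScore,
    coefficient_of_variation,
    composite_score,
    kendalls_w,
    read_scores_csv,
    sample_size_two_means,
    score_table_summary,
)


def _score(a, c, v, o, reader="r1", study="s1", frr="50"):
    return ReaderScore(reader, study, frr, a, c, v, o)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "subs, expected", [((5, 5, 5, 5), 20), ((1, 1, 1, 1), 4), ((3, 4, 2, 5), 14)]
    )
    def test_sum_of_four_items(self, subs, expected):
        assert composite_score(_score(*subs)) == expected

    def test_range_is_attained_only_at_extremes(self):
        composites = [
            composite_score(_score(*combo))
            for combo in itertools.product((1, 5), repeat=4)
        ]
        assert min(composites) == 4 and max(composites) == 20

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range_subscores_rejected(self, bad):
        with pytest.raises(ValueError):
            _score(bad, 3, 3, 3)


def brute_force_w(ratings):
    """W from the rank-sum-variance definition with mid-ranks."""
    m, n = ratings.shape
    ranks = np.array([stats.rankdata(row) for row in ratings])
    rank_sums = ranks.sum(axis=0)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    t = sum(
        (counts**3 - counts).sum()
        for counts in (np.unique(row, return_counts=True)[1] for row in ratings)
    )
    return 12 * s / (m**2 * (n**3 - n) - m * t)


class TestKendallsW:
    def test_perfect_concordance(self):
        ratings = np.tile(np.array([3.0, 1.0, 4.0, 2.0, 5.0]), (3, 1))
        result = kendalls_w(ratings)
        assert result["W"] == pytest.approx(1.0)
        assert 0 < result["p"] < 0.05

    def test_reversed_rankings_match_oracle(self):
        ratings = np.array([[1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        result = kendalls_w(ratings)
        assert result["W"] == pytest.approx(brute_force_w(ratings), rel=1e-12)
        assert result["W"] == pytest.approx(0.0, abs=1e-12)

    def test_no_tie_classical_formula(self):
        rng = np.random.default_rng(2)
        ratings = np.array([rng.permutation(7) + 1 for _ in range(4)], dtype=float)
        m, n = ratings.shape
        ranks = ratings  # permutations of 1..n are already ranks
        s = ((ranks.sum(axis=0) - ranks.sum(axis=0).mean()) ** 2).sum()
        classical = 12 * s / (m**2 * (n**3 - n))
        assert kendalls_w(ratings)["W"] == pytest.approx(classical, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tied_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ratings = rng.integers(1, 6, size=(3, 10)).astype(float)
        result = kendalls_w(ratings)
        assert result["W"] == pytest.approx(brute_force_w(ratings), rel=1e-12)
        # chi-square approximation ties W and p together
        assert result["chi2"] == pytest.approx(3 * 9 * result["W"])

    def test_friedman_cross_check(self):
        # scipy's Friedman statistic equals m(n-1)W with tie correction
        rng = np.random.default_rng(11)
        ratings = rng.integers(1, 6, size=(4, 8)).astype(float)
        result = kendalls_w(ratings)
        friedman = stats.friedmanchisquare(*ratings.T)
        assert result["chi2"] == pytest.approx(friedman.statistic, rel=1e-10)

    def test_invariances(self):
        rng = np.random.default_rng(3)
        ratings = rng.integers(1, 6, size=(3, 8)).astype(float)
        w = kendalls_w(ratings)["W"]
        # relabeling subjects
        perm = rng.permutation(8)
        assert kendalls_w(ratings[:, perm])["W"] == pytest.approx(w)
        # strictly monotone transform of one rater's scores
        transformed = ratings.copy()
        transformed[1] = transformed[1] ** 2 + 3
        assert kendalls_w(transformed)["W"] == pytest.approx(w)

    def test_undefined_for_constant_ratings(self):
        with pytest.raises(ValueError):
            kendalls_w(np.full((3, 5), 2.0))
        with pytest.raises(ValueError):
            kendalls_w(np.array([1.0, 2.0, 3.0]))


class TestCoefficientOfVariation:
    def test_values(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0
        assert coefficient_of_variation([10, 20, 30]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        values = [3.0, 7.0, 11.0]
        assert coefficient_of_variation([7 * v for v in values]) == pytest.approx(
            coefficient_of_variation(values)
        )

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestSampleSize:
    def test_reader_study_design_values(self):
        assert sample_size_two_means(16, 2, 13, 3, alpha=0.05, power=0.75) == 12

    def test_enormous_effect_hits_floor(self):
        assert sample_size_two_means(10, 1, 0, 1, alpha=0.05, power=0.75) == 2

    def test_monotone_in_power(self):
        n_75 = sample_size_two_means(16, 2, 13, 3, power=0.75)
        n_90 = sample_size_two_means(16, 2, 13, 3, power=0.90)
        assert n_90 > n_75

    def test_agrees_with_normal_approximation_for_large_n(self):
        mean1, sd = 0.3, 1.0
        n = sample_size_two_means(mean1, sd, 0.0, sd, alpha=0.05, power=0.8)
        d = mean1 / sd
        z = stats.norm.ppf(1 - 0.025) + stats.norm.ppf(0.8)
        approx = 2 * (z / d) ** 2
        assert n >= 30
        assert abs(n - approx) <= 2  # noncentral t needs about one extra subject

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        d = 3 / np.sqrt((4 + 9) / 2)
        n_sm = TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.75)
        assert sample_size_two_means(16, 2, 13, 3, 0.05, 0.75) == int(np.ceil(n_sm))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_size_two_means(10, 1, 10, 1)  # zero effect
        with pytest.raises(ValueError):
            sample_size_two_means(10, 0, 12, 1)
        with pytest.raises(ValueError):
            sample_size_two_means(10, 1, 12, 1, alpha=1.5)


class TestScoreTable:
    def _synthetic_scores(self, seed=0):
        rng = np.random.default_rng(seed)
        scores = []
        for frr in ("50", "66", "75"):
            for reader in ("r1", "r2", "r3"):
                for study in range(16):
                    subs = rng.integers(1, 6, size=4)
                    scores.append(
                        ReaderScore(reader, f"s{study}", frr, *map(int, subs))
                    )
        return scores

    def test_matches_brute_force_group_by(self):
        scores = self._synthetic_scores()
        table = score_table_summary(scores)
        # brute force for one group
        group = [s.composite for s in scores if s.frr_level == "66" and s.reader_id == "r2"]
        row = table[(table["frr_level"] == "66") & (table["reader_id"] == "r2")].iloc[0]
        assert row["n"] == len(group) == 16
        assert row["mean"] == pytest.approx(np.mean(group))
        assert row["sd"] == pytest.approx(np.std(group, ddof=1))
        half = stats.t.ppf(0.975, 15) * np.std(group, ddof=1) / np.sqrt(16)
        assert row["ci95_low"] == pytest.approx(np.mean(group) - half)
        # per-level totals present
        totals = table[table["reader_id"] == "all"]
        assert set(totals["frr_level"]) == {"50", "66", "75"}
        assert (totals["n"] == 48).all()

    def test_single_score_blanks_dispersion(self):
        table = score_table_summary([_score(3, 3, 3, 3)])
        row = table.iloc[0]
        assert row["n"] == 1
        assert np.isnan(row["sd"]) and np.isnan(row["ci95_low"])

    def test_constant_scores_zero_width_ci(self):
        scores = [_score(4, 4, 4, 4, reader="r1", study=f"s{i}") for i in range(5)]
        row = score_table_summary(scores).iloc[0]
        assert row["sd"] == 0.0
        assert row["ci95_low"] == row["ci95_high"] == row["mean"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_table_summary([])


def test_scores_csv_round_trip(tmp_path):
    import pandas as pd

    rows = [
        {"reader_id": "r1", "study_id": "s1", "frr": "50",
         "arterial": 4, "capillary": 3, "venous": 5, "overall_quality": 4},
        {"reader_id": "r2", "study_id": "s1", "frr": "50",
         "arterial": 2, "capillary": 2, "venous": 3, "overall_quality": 3},
    ]
    path = tmp_path / "scores.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    scores = read_scores_csv(path)
    assert [s.composite for s in scores] == [16, 10]
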