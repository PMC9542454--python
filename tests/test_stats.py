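import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from faceemg import stats
from faceemg.synthetic_data import CohortConfig, default_study_schedule, simulate_cohort
from faceemg.types import DegenerateComparisonError


def brute_friedman_chi2(matrix):
    """Tie-corrected Friedman statistic straight from the rank definition."""
    n, k = matrix.shape
    ranks = np.array([sstats.rankdata(row) for row in matrix])
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    ties = sum(
        np.sum(np.unique(row, return_counts=True)[1] ** 3
               - np.unique(row, return_counts=True)[1])
        for row in matrix
    )
    c = 1.0 - ties / (n * k * (k**2 - 1))
    return 0.0 if c <= 0 else chi2 / c


def exact_wilcoxon_p(d):
    """Two-sided exact p by enumerating all sign assignments of |d| ranks."""
    d = d[d != 0]
    n = d.size
    ranks = sstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    dev = abs(w_obs - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2.0**n


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        """n identical orderings of k=3 conditions give chi2 = 2n."""
        matrix = np.tile([1.0, 2.0, 3.0], (5, 1))
        res = stats.friedman(matrix, ("a", "b", "c"))
        assert res.chi2 == pytest.approx(10.0)
        assert res.df == 2
        assert res.mean_ranks == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_constant_matrix_is_null(self):
        res = stats.friedman(np.full((6, 3), 2.5))
        assert res.chi2 == 0.0
        assert res.p == 1.0
        assert all(v == 2.0 for v in res.mean_ranks.values())

    def test_mean_rank_average_is_centered(self, rng):
        matrix = rng.normal(size=(10, 4))
        res = stats.friedman(matrix)
        assert np.mean(list(res.mean_ranks.values())) == pytest.approx(2.5)

    def test_matches_definition_and_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(3, 6))
            matrix = np.round(rng.normal(size=(n, k)), 1)  # induces ties
            res = stats.friedman(matrix)
            assert res.chi2 == pytest.approx(brute_friedman_chi2(matrix),
                                             abs=1e-10)
            if not np.any([np.ptp(row) == 0 for row in matrix]):
                ref = sstats.friedmanchisquare(*matrix.T)
                assert res.chi2 == pytest.approx(ref.statistic, abs=1e-10)
                assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_missing_cells_rejected(self):
        matrix = np.ones((4, 3))
        matrix[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            stats.friedman(matrix)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateComparisonError, match="zero"):
            stats.wilcoxon_paired(x, x)

    def test_statistic_and_z_match_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 1.0, size=n)
            res = stats.wilcoxon_paired(x, y)
            ref = sstats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                                  method="approx")
            assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)
            assert abs(res.z) == pytest.approx(abs(ref.zstatistic), rel=1e-9)

    def test_sign_convention(self, rng):
        x = rng.normal(size=20)
        res = stats.wilcoxon_paired(x + 1.0, x)
        assert res.z > 0
        res = stats.wilcoxon_paired(x - 1.0, x)
        assert res.z < 0

    def test_normal_approximation_tracks_exact_enumeration(self, rng):
        """The approximate p tracks the exact permutation p within the
        documented error bound of the tie-free normal approximation without
        continuity correction: <= 0.08 at n = 8 (the exact null is coarse,
        with 2^-8 probability lumps), shrinking as n grows."""
        for _ in range(100):
            n = int(rng.integers(8, 13))
            d = rng.normal(0.4, 1.0, size=n)
            d = np.where(d == 0, 0.1, d)
            x = np.zeros(n) + d
            y = np.zeros(n)
            res = stats.wilcoxon_paired(x, y)
            bound = 0.08 if n < 10 else 0.05
            assert abs(res.p_raw - exact_wilcoxon_p(d)) <= bound

    def test_all_positive_differences_minimal_p(self):
        """x = y + 1 at n=20: the exact two-sided p is 2 * 2^-20."""
        y = np.linspace(0, 1, 20)
        x = y + 1.0
        d = x - y
        assert exact_wilcoxon_p(d) == pytest.approx(2 * 2.0**-20)
        res = stats.wilcoxon_paired(x, y)
        assert res.z > 0
        assert res.p_raw < 1e-4

    def test_too_few_nonzero_pairs_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 4.5])
        with pytest.raises(DegenerateComparisonError, match="< 5"):
            stats.wilcoxon_paired(x, y)


class TestBonferroniAndStars:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 6, 0.06), (0.3, 6, 1.0), (0.002, 18, 0.036)]
    )
    def test_adjustment(self, p, m, expected):
        assert stats.bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_monotone_and_capped(self, rng):
        ps = np.sort(rng.uniform(size=20))
        for m in (1, 6, 18):
            adj = [stats.bonferroni_adjust(p, m) for p in ps]
            assert all(a <= b for a, b in zip(adj, adj[1:]))
            assert all(a <= 1.0 for a in adj)
        assert stats.bonferroni_adjust(1.0, 18) == 1.0

    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.5, "ns"), (0.051, "ns"), (0.05, "*"), (0.03, "*"),
            (0.01, "**"), (0.002, "**"), (0.001, "***"), (2e-4, "***"),
            (1e-4, "****"), (5e-5, "****"), (0.0, "****"),
        ],
    )
    def test_annotation_scheme(self, p, stars):
        assert stats.annotate(p) == stars


class TestSegmentPearson:
    def test_exact_line_in_upper_segment(self):
        levels = np.array([5, 6, 7, 8, 9, 1, 2])
        values = np.where(levels >= 5, 0.1 * levels, 0.9)
        res = stats.segment_pearson(levels, values, 5, 9)
        assert res.r == pytest.approx(1.0)
        assert res.n == 5

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.integers(1, 10, size=n).astype(float)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=n)
            res = stats.segment_pearson(x, y, 1, 9)
            r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert res.r == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateComparisonError, match="variance"):
            stats.segment_pearson([5, 5, 5], [0.1, 0.2, 0.3], 1, 9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            stats.segment_pearson([1, 2], [0.1, 0.2], 1, 9)


class TestQuadraticTrend:
    def test_exact_parabola_recovered(self):
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        y = (x - 5.0) ** 2
        fit = stats.quadratic_trend(x, y)
        assert fit.quadratic == pytest.approx(1.0, abs=1e-9)
        assert fit.linear == pytest.approx(-10.0, abs=1e-9)
        assert fit.intercept == pytest.approx(25.0, abs=1e-9)

    def test_straight_line_has_no_curvature(self):
        x = np.array([1.0, 2.0, 4.0, 6.0, 9.0])
        fit = stats.quadratic_trend(x, 0.3 * x + 1.0)
        assert fit.quadratic == pytest.approx(0.0, abs=1e-9)

    def test_noisy_parabola_parameter_recovery(self, rng):
        x = rng.integers(1, 10, size=200).astype(float)
        curvature = 0.05
        y = curvature * (x - 5.0) ** 2 + rng.normal(0, 0.05, size=200)
        fit = stats.quadratic_trend(x, y)
        assert abs(fit.quadratic - curvature) <= 3 * fit.se[0]

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            stats.quadratic_trend([1, 1, 2, 2], [0.1, 0.2, 0.3, 0.4])


def _means_frame(n_subjects, conditions, channel_values, scheme, rng):
    """Synthetic condition-mean table: channel_values maps channel to
    per-condition population means."""
    rows = []
    for s in range(n_subjects):
        for ch, cond_means in channel_values.items():
            for cond in conditions:
                rows.append(
                    {
                        "subject_id": f"s{s:02d}",
                        "channel": ch,
                        "scheme": scheme,
                        "condition": cond,
                        "value": float(
                            np.clip(rng.normal(cond_means[cond], 0.05), 0, 1)
                        ),
                    }
                )
    return pd.DataFrame(rows)


class TestPairedAmplitudeAnalysis:
    def test_rating_bin_family_has_six_tests(self, rng):
        channel_values = {
            ch: {"V_negative": 0.3, "V_positive": 0.6}
            for ch in stats.MODALITIES
        }
        means = _means_frame(12, ("V_negative", "V_positive"), channel_values,
                             "valence_bin", rng)
        table = stats.paired_amplitude_analysis(means, "valence_bin")
        assert len(table) == 6
        assert (table["m"] == 6).all()
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()

    def test_video_type_family_has_eighteen_tests(self, rng):
        conds = ("W_negative", "W_neutral", "W_positive")
        channel_values = {
            ch: {"W_negative": 0.4, "W_neutral": 0.2, "W_positive": 0.6}
            for ch in stats.MODALITIES
        }
        means = _means_frame(12, conds, channel_values, "video_type", rng)
        table = stats.paired_amplitude_analysis(means, "video_type")
        assert len(table) == 18
        assert (table["m"] == 18).all()
        pairs = set(zip(table["condition_a"], table["condition_b"]))
        assert len(pairs) == 3

    def test_small_cell_recorded_as_degenerate(self, rng):
        channel_values = {
            ch: {"V_negative": 0.3, "V_positive": 0.6}
            for ch in stats.MODALITIES
        }
        means = _means_frame(3, ("V_negative", "V_positive"), channel_values,
                             "valence_bin", rng)
        table = stats.paired_amplitude_analysis(means, "valence_bin")
        assert len(table) == 6
        assert (table["annotation"] == "degenerate").all()

    def test_annotation_consistent_with_adjusted_p(self, rng):
        channel_values = {
            ch: {"V_negative": 0.3, "V_positive": 0.7}
            for ch in stats.MODALITIES
        }
        means = _means_frame(20, ("V_negative", "V_positive"), channel_values,
                             "valence_bin", rng)
        table = stats.paired_amplitude_analysis(means, "valence_bin")
        for _, row in table.iterrows():
            assert row["annotation"] == stats.annotate(row["p_adj"])


class TestManipulationCheck:
    def test_synthetic_ratings_recover_category_means(self):
        """Ratings simulated with the default profile land near the
        configured per-category means at n = 38."""
        cohort = simulate_cohort(CohortConfig(n_subjects=38, seed=5))
        check = stats.manipulation_check(cohort.all_ratings(), cohort.schedule)
        table = check.table.set_index(["category", "scale"])
        expected = {
            ("neutral", "valence"): 4.65, ("negative", "valence"): 3.18,
            ("positive", "valence"): 6.60, ("neutral", "arousal"): 3.41,
            ("negative", "arousal"): 6.67, ("positive", "arousal"): 5.88,
        }
        for key, mean in expected.items():
            assert table.loc[key, "mean"] == pytest.approx(mean, abs=0.5)
        for scale in ("valence", "arousal"):
            assert check.friedman[scale].p < 0.001
            assert check.pairwise[scale] is not None
        # negative videos rated lower-valence than neutral ones
        pw = check.pairwise["valence"].set_index(["condition_a", "condition_b"])
        assert pw.loc[("neutral", "negative"), "z"] > 0

    def test_identical_ratings_are_null(self):
        from faceemg.types import RatingRecord

        sched = default_study_schedule("s01")
        ratings = [
            RatingRecord(f"s{i:02d}", ev.video_id, 5, 5)
            for i in range(6)
            for ev in sched.events
        ]
        check = stats.manipulation_check(ratings, sched)
        for scale in ("valence", "arousal"):
            assert check.friedman[scale].chi2 == 0.0
            assert check.pairwise[scale] is None
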