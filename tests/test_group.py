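"""Group inference: permutation null, band attribution, mixed ANOVA,
correlations and trial-series autocorrelation."""

import numpy as np
import pytest

from prestim import (
    DataError,
    SubjectDecoding,
    accuracy_correlation,
    band_argmax_weights,
    fcz_gamma_correlation,
    lateralization_anova,
    per_frequency_correlation,
    permutation_null,
    trial_autocorrelation,
)
from test_decoding import cluster_features, make_features


def make_result(weight_map, freqs, binomial_p=0.001, labels=None):
    weight_map = np.asarray(weight_map, dtype=float)
    return SubjectDecoding(
        accuracy=0.7,
        n_correct=56,
        n_trials=80,
        fold_assignment=np.ones(80, dtype=int),
        binomial_p=binomial_p,
        weight_map=weight_map,
        freq_axis=np.asarray(freqs, dtype=float),
        channel_labels=tuple(f"ch{i}" for i in range(weight_map.shape[0]))
        if labels is None else tuple(labels),
        frequency_range_used=(float(freqs[0]), float(freqs[-1])),
    )


class TestPermutationNull:
    def test_counting_formula_for_separable_cohort(self):
        feats, labels = cluster_features(delta=10.0, seed=0)
        res = permutation_null([feats], [labels], n_iterations=99, seed=0, observed=1.0)
        assert res.p_value == pytest.approx(1.0 / 100.0)
        assert len(res.null_distribution) == 99

    def test_same_seed_reproduces_null(self):
        feats, labels = cluster_features(delta=0.0, seed=1)
        a = permutation_null([feats], [labels], n_iterations=20, seed=5, observed=0.6)
        b = permutation_null([feats], [labels], n_iterations=20, seed=5, observed=0.6)
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)

    def test_null_mean_near_chance(self):
        feats, labels = cluster_features(delta=0.0, seed=2, n_per_class=20)
        res = permutation_null([feats], [labels], n_iterations=100, seed=3, observed=0.5)
        assert abs(res.null_distribution.mean() - 0.5) < 0.05

    def test_requires_at_least_one_iteration(self):
        feats, labels = cluster_features()
        with pytest.raises(DataError):
            permutation_null([feats], [labels], n_iterations=0, seed=0, observed=0.5)


class TestBandArgmax:
    freqs = np.arange(4.0, 121.0)

    def test_single_nonzero_weight_wins_its_band(self):
        w = np.zeros((3, len(self.freqs)))
        w[1, np.where(self.freqs == 80.0)[0][0]] = 0.5
        winners, counts = band_argmax_weights([make_result(w, self.freqs)])
        assert winners == ["high_gamma"]
        assert counts["high_gamma"] == 1

    def test_tie_broken_toward_lower_frequency_band(self):
        w = np.zeros((1, len(self.freqs)))
        w[0, np.where(self.freqs == 5.0)[0][0]] = 0.7
        w[0, np.where(self.freqs == 80.0)[0][0]] = 0.7
        winners, _ = band_argmax_weights([make_result(w, self.freqs)])
        assert winners == ["theta"]

    def test_nonsignificant_subjects_excluded(self):
        w = np.zeros((1, len(self.freqs)))
        w[0, 0] = 1.0
        winners, counts = band_argmax_weights(
            [make_result(w, self.freqs, binomial_p=0.5)])
        assert winners == [None]
        assert sum(counts.values()) == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        results = [make_result(rng.standard_normal((4, len(self.freqs))), self.freqs)
                   for _ in range(20)]
        winners, _ = band_argmax_weights(results)
        from prestim import BANDS

        for res, got in zip(results, winners):
            best, bv = None, -1.0
            for b in sorted(BANDS, key=lambda b: b.lo):
                mask = (self.freqs >= b.lo) & (self.freqs <= b.hi)
                v = np.abs(res.weight_map[:, mask]).max()
                if v > bv:
                    best, bv = b.name, v
            assert got == best

    def test_unassigned_band_frequencies_never_win(self):
        # 25-29 Hz belongs to no band; a huge weight there must not count
        w = np.zeros((1, len(self.freqs)))
        w[0, np.where(self.freqs == 27.0)[0][0]] = 5.0
        w[0, np.where(self.freqs == 70.0)[0][0]] = 0.1
        winners, _ = band_argmax_weights([make_result(w, self.freqs)])
        assert winners == ["high_gamma"]


def anova_oracle(c5, c6, site):
    """Closed-form check via the two-sample t-test on difference scores:
    for a 2-level within factor the site x electrode interaction F equals
    the squared t comparing (C6 - C5) between site groups."""
    from scipy import stats

    d = np.asarray(c6) - np.asarray(c5)
    site = np.asarray(site)
    t, p = stats.ttest_ind(d[site == "left"], d[site == "right"], equal_var=True)
    return t * t, p


class TestLateralizationAnova:
    def test_all_equal_weights_give_zero_F(self):
        res = lateralization_anova([1, 1, 1, 1], [1, 1, 1, 1],
                                   ["left", "left", "right", "right"])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_perfect_crossed_pattern_gives_infinite_F(self):
        res = lateralization_anova(
            [-1, -1, 1, 1], [1, 1, -1, -1], ["left", "left", "right", "right"])
        assert np.isinf(res.F)
        assert res.p == 0.0

    def test_matches_difference_score_t_squared(self):
        rng = np.random.default_rng(5)
        c5 = rng.standard_normal(8)
        c6 = rng.standard_normal(8)
        site = np.array(["left"] * 5 + ["right"] * 3)
        res = lateralization_anova(c5, c6, site)
        F_oracle, p_oracle = anova_oracle(c5, c6, site)
        assert res.F == pytest.approx(F_oracle, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, rel=1e-10)
        assert res.df1 == 1 and res.df2 == 6

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        n = 12
        c5 = rng.standard_normal(n)
        c6 = rng.standard_normal(n)
        site = np.array(["left"] * 7 + ["right"] * 5)
        res = lateralization_anova(c5, c6, site)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "electrode": ["C5", "C6"] * n,
            "site": np.repeat(site, 2),
            "w": np.column_stack([c5, c6]).ravel(),
        })
        aov = pingouin.mixed_anova(df, dv="w", within="electrode",
                                   subject="subject", between="site")
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        assert res.F == pytest.approx(float(inter["F"]), rel=1e-8)
        assert res.p == pytest.approx(float(inter["p_unc"]), rel=1e-8)

    def test_single_subject_site_group_is_error(self):
        with pytest.raises(DataError, match="fewer than 2"):
            lateralization_anova([1, 2, 3], [1, 2, 3], ["left", "left", "right"])


class TestCorrelations:
    def test_identical_vectors_correlate_perfectly(self):
        x = np.array([0.5, 0.6, 0.7, 0.9])
        res = accuracy_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        x = np.array([0.1, 0.4, 0.8, 0.3])
        res = accuracy_correlation(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_sampling_distribution_recovers_rho(self):
        rng = np.random.default_rng(7)
        rho, n = 0.8, 33
        rs = []
        for _ in range(500):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            rs.append(accuracy_correlation(x, y).r)
        assert abs(np.mean(rs) - rho) < 0.03

    def test_agrees_with_covariance_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 20))
        res = accuracy_correlation(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res.r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(DataError, match="zero-variance"):
            accuracy_correlation([1, 1, 1], [1, 2, 3])

    def test_missing_channel_is_error(self):
        rng = np.random.default_rng(9)
        feats = [make_features(rng.random((4, 2, 117)) + 0.1,
                               freqs=np.arange(4.0, 121.0)) for _ in range(4)]
        with pytest.raises(DataError, match="not found"):
            fcz_gamma_correlation(feats, feats, channel="FCz")


class TestPerFrequencyCorrelation:
    def make_cohort(self, n_subj=20, seed=10, couple_from=60.0):
        rng = np.random.default_rng(seed)
        freqs = np.arange(4.0, 121.0)
        pre, post = [], []
        subj_level = rng.standard_normal(n_subj)
        for s in range(n_subj):
            base_pre = rng.random((6, 1, len(freqs))) + 10.0
            base_post = rng.random((6, 1, len(freqs))) + 10.0
            mask = freqs >= couple_from
            base_pre[:, :, mask] += subj_level[s]
            base_post[:, :, mask] += subj_level[s]
            pre.append(make_features(base_pre, freqs=freqs, labels=("FCz",)))
            post.append(make_features(base_post, freqs=freqs, labels=("FCz",)))
        return pre, post, freqs

    def test_planted_coupling_confined_to_high_frequencies(self):
        pre, post, freqs = self.make_cohort()
        res = per_frequency_correlation(pre, post, channel="FCz")
        sig_freqs = freqs[res["significant"]]
        assert len(sig_freqs) > 0
        assert (sig_freqs >= 60.0).all()

    def test_alpha_zero_gives_empty_set(self):
        pre, post, _ = self.make_cohort(n_subj=8)
        res = per_frequency_correlation(pre, post, channel="FCz", alpha=0.0)
        assert not res["significant"].any()

    def test_bonferroni_threshold_arithmetic(self):
        pre, post, _ = self.make_cohort(n_subj=8)
        res = per_frequency_correlation(pre, post, channel="FCz", alpha=0.05)
        assert res["bonferroni_threshold"] == pytest.approx(0.05 / 117)
        np.testing.assert_array_equal(res["significant"],
                                      res["p"] < 0.05 / 117)


class TestTrialAutocorrelation:
    def test_ar1_recovery(self):
        rng = np.random.default_rng(11)
        phi, n = 0.5, 2000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + np.sqrt(1 - phi ** 2) * rng.standard_normal()
        res = trial_autocorrelation(x)
        assert abs(res["acf"][0] - phi) < 0.05

    def test_white_noise_flag_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        flags = []
        for _ in range(500):
            res = trial_autocorrelation(rng.standard_normal(80))
            flags.append(res["exceeds"])
        rate = np.mean(flags)
        assert 0.03 < rate < 0.08

    def test_constant_series_is_error(self):
        with pytest.raises(DataError, match="constant"):
            trial_autocorrelation(np.ones(100))

    def test_short_series_is_error(self):
        with pytest.raises(DataError, match="too short"):
            trial_autocorrelation(np.arange(20), max_lag=20)
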