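"""Summary statistics and analytic variance expectations."""

import numpy as np
import pandas as pd
import pytest

from polyadapt import summaries


def trajectory(means, start=0):
    return pd.DataFrame({"generation": np.arange(start, start + len(means)),
                         "mean_trait": means})


class TestTimeToOptimum:
    def test_first_crossing_in_n_anc_units(self):
        means = [0.0] * 7 + [10.0, 10.0]
        assert summaries.time_to_optimum(trajectory(means), 10.0, 1000) == pytest.approx(0.007)

    def test_missing_when_never_reached(self):
        means = [0.0, 5.0, 9.8]
        assert np.isnan(summaries.time_to_optimum(trajectory(means), 10.0, 1000))

    def test_uses_99_percent_rule(self):
        means = [0.0, 9.91, 9.95]
        assert summaries.time_to_optimum(trajectory(means), 10.0, 100) == pytest.approx(0.01)


class TestAdaptationRate:
    def test_arithmetic(self):
        means = [0.0] * 100 + [10.0]
        assert summaries.adaptation_rate(trajectory(means), 1.0, 10.0) == pytest.approx(0.1)

    def test_doubling_generations_halves_rate(self):
        fast = trajectory([0.0] * 50 + [10.0])
        slow = trajectory([0.0] * 100 + [10.0])
        assert summaries.adaptation_rate(fast, 1.0, 10.0) == pytest.approx(
            2 * summaries.adaptation_rate(slow, 1.0, 10.0))

    def test_invariant_to_common_offset(self):
        base = trajectory(np.linspace(0, 10, 60))
        shifted = trajectory(np.linspace(3, 13, 60))
        assert summaries.adaptation_rate(base, 0.25, 10.0) == pytest.approx(
            summaries.adaptation_rate(shifted, 0.25, 13.0), rel=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            summaries.adaptation_rate(trajectory([0.0, 10.0]), 0.0, 10.0)


class TestSFS:
    def test_single_site_occupies_one_bin(self):
        out = summaries.sfs([0.5], n_bins=20)
        assert out["count"].sum() == 1
        assert out.loc[out["count"] == 1, "bin_left"].iloc[0] == 0.5

    def test_neutral_reference_scales_to_observed_sites(self, rng):
        freqs = rng.uniform(0.01, 0.99, size=200)
        out = summaries.sfs(freqs, n_bins=10, two_n=400)
        assert out["neutral_expected"].sum() == pytest.approx(200)
        # 1/i reference is decreasing in frequency
        assert out["neutral_expected"].iloc[0] > out["neutral_expected"].iloc[-1]

    def test_empty_snapshot(self):
        out = summaries.sfs([], n_bins=5)
        assert out["count"].sum() == 0

    def test_high_frequency_fraction(self):
        assert summaries.high_frequency_fraction([0.1, 0.6, 0.9, 0.4]) == 0.5
        assert np.isnan(summaries.high_frequency_fraction([]))


class TestVarianceExpectations:
    @pytest.mark.parametrize("mu, v_s, expected", [
        (3e-3, 1.0, 0.012),
        (0.0, 123.0, 0.0),
        (3e-3, 50.0, 0.6),
    ])
    def test_house_of_cards(self, mu, v_s, expected):
        assert summaries.hoc_expectation(mu, v_s) == pytest.approx(expected)

    def test_stochastic_house_of_cards(self):
        assert summaries.stochastic_hoc_expectation(3e-3, 1.0, 10_000, 0.05) == \
            pytest.approx(0.012 / 1.04)
        assert summaries.stochastic_hoc_expectation(3e-3, 50.0, 10_000, 0.9) == \
            pytest.approx(0.6 / (1 + 50 / 8100))

    def test_large_effects_recover_deterministic_hoc(self):
        shc = summaries.stochastic_hoc_expectation(3e-3, 5.0, 1000, 1e6)
        assert shc == pytest.approx(summaries.hoc_expectation(3e-3, 5.0), rel=1e-6)


class TestFixationAndSegregatingStats:
    def test_sign_partition(self):
        fx = pd.DataFrame({"effect": [0.1, -0.02, 0.3]})
        s = summaries.fixation_stats(fx)
        assert s["n_fixations"] == 3
        assert s["mean_effect_positive_fixations"] == pytest.approx(0.2)
        assert s["mean_effect_negative_fixations"] == pytest.approx(-0.02)

    def test_missing_sign_class(self):
        s = summaries.fixation_stats(pd.DataFrame({"effect": [0.1, 0.2]}))
        assert np.isnan(s["mean_effect_negative_fixations"])
        empty = summaries.fixation_stats(pd.DataFrame({"effect": []}))
        assert empty["n_fixations"] == 0

    def test_segregating_descriptors(self):
        seg = pd.DataFrame({"effect": [0.1, -0.1, 0.2, -0.3],
                            "frequency": [0.5, 0.25, 0.1, 0.05]})
        s = summaries.segregating_stats(seg)
        assert s["prop_negative_seg"] == 0.5
        assert s["mean_freq_positive_seg"] == pytest.approx(0.3)
        assert s["mean_freq_negative_seg"] == pytest.approx(0.15)
        all_pos = summaries.segregating_stats(
            pd.DataFrame({"effect": [0.1], "frequency": [0.2]}))
        assert all_pos["prop_negative_seg"] == 0.0
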