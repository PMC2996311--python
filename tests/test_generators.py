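"""Generator behaviour: truncation, quotas, moments, and reproducibility."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from boutlaw import (
    BoutSample,
    MarkovSpec,
    MixtureSpec,
    PowerLawModel,
    ExponentialMixtureModel,
    draw_exponential_mixture,
    draw_power_law,
    quotas_from_proportions,
    sample_from_fitted,
    simulate_markov_hypnogram,
)


class TestPowerLaw:
    def test_inverse_cdf_boundary(self):
        # u = 0 maps to the lower threshold exactly
        assert PowerLawModel(3.0, 1.0).ppf(0.0) == 1.0
        assert PowerLawModel(2.5, 2.0).ppf(0.0) == 2.0

    def test_log_moment_matches_pareto(self):
        # E log(x/x_min) = 1/(alpha-1) = 0.5 for alpha = 3
        s = draw_power_law(10**6, 3.0, 1.0, seed=11)
        assert abs(np.log(s.durations).mean() - 0.5) < 0.005

    def test_all_draws_above_threshold(self):
        s = draw_power_law(10000, 3.0, 1.0, seed=3)
        assert s.durations.min() >= 1.0

    @pytest.mark.parametrize("alpha", [1.0, 0.5, -2.0])
    def test_nonnormalizable_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            draw_power_law(10, alpha, 1.0, seed=0)

    def test_two_sample_ks_against_scipy_pareto(self):
        # independent textbook law: Pareto with shape alpha-1
        s = draw_power_law(10**5, 3.0, 1.0, seed=5)
        ref = stats.pareto(b=2.0).rvs(10**5, random_state=99)
        assert stats.ks_2samp(s.durations, ref).pvalue > 0.001


class TestExponentialMixture:
    def test_truncated_mean_is_one_plus_tau(self):
        # left truncation at 1 plus memorylessness: mean = 1 + tau
        s = draw_exponential_mixture(MixtureSpec(((5.0, 10**6),)), seed=7)
        assert abs(s.durations.mean() - 6.0) < 0.02

    def test_quotas_exact_and_degenerate_component(self):
        spec = MixtureSpec(((1.0, 40), (15.0, 0)))
        s = draw_exponential_mixture(spec, seed=1)
        assert s.n == 40
        assert spec.n_draws == (40, 0)

    def test_truncation_rule(self):
        s = draw_exponential_mixture(MixtureSpec(((1.0, 5000),)), seed=2)
        assert s.durations.min() >= 1.0

    def test_truncation_switch_off(self):
        s = draw_exponential_mixture(
            MixtureSpec(((1.0, 5000),)), seed=2, truncate_at_one=False)
        assert (s.durations < 1.0).any()

    def test_two_sample_ks_against_shifted_exponential(self):
        s = draw_exponential_mixture(MixtureSpec(((5.0, 10**5),)), seed=8)
        ref = 1.0 + stats.expon(scale=5.0).rvs(10**5, random_state=77)
        assert stats.ks_2samp(s.durations, ref).pvalue > 0.001

    def test_zero_quota_component_consumes_no_randomness(self):
        # degenerate two-component spec must equal the mono-exponential sample
        two = draw_exponential_mixture(MixtureSpec(((1.0, 0), (12.0, 500))), seed=6)
        mono = draw_exponential_mixture(MixtureSpec(((12.0, 500),)), seed=6)
        np.testing.assert_array_equal(two.durations, mono.durations)

    @pytest.mark.parametrize("bad", [
        ((0.0, 10),),
        ((1.0, 0),),
        ((1.0, 5), (2.0, 5), (3.0, 5), (4.0, 5)),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            MixtureSpec(bad)


class TestMarkov:
    def test_sleep_bout_mean_matches_geometric(self):
        # geometric dwell time: mean 1/(1 - p_stay) = 10
        sleep, _ = simulate_markov_hypnogram(
            MarkovSpec(0.9, 0.9, 4000), seed=13)
        se = np.sqrt(0.9) / 0.1 / np.sqrt(4000)  # geometric SD / sqrt(n)
        assert abs(sleep.durations.mean() - 10.0) < 3 * se

    def test_small_stay_probability_gives_unit_bouts(self):
        sleep, _ = simulate_markov_hypnogram(MarkovSpec(0.01, 0.5, 2000), seed=4)
        assert (sleep.durations == 1.0).mean() > 0.95

    def test_two_sample_ks_against_scipy_geometric(self):
        sleep, _ = simulate_markov_hypnogram(MarkovSpec(0.9, 0.9, 10**5), seed=21)
        ref = stats.geom(p=0.1).rvs(10**5, random_state=55)
        assert stats.ks_2samp(sleep.durations, ref).pvalue > 0.001

    def test_bout_count_and_support(self):
        sleep, wake = simulate_markov_hypnogram(MarkovSpec(0.8, 0.6, 400), seed=9)
        assert sleep.n == wake.n == 400
        assert sleep.durations.min() >= 1.0
        assert np.all(sleep.durations == np.floor(sleep.durations))


class TestSampleFromFitted:
    def test_mono_exponential_truncated_mean(self):
        model = ExponentialMixtureModel((1.0,), (4.0,))
        s = sample_from_fitted(model, 10**6, seed=17)
        assert abs(s.durations.mean() - 5.0) < 0.02
        assert s.durations.min() >= 1.0

    def test_power_law_model_equals_direct_generator(self):
        model = PowerLawModel(3.0, 1.0)
        a = sample_from_fitted(model, 1000, seed=23)
        b = draw_power_law(1000, 3.0, 1.0, seed=23)
        np.testing.assert_array_equal(a.durations, b.durations)

    def test_mixture_component_weights(self):
        # component choice prob w_i = a_i tau_i exp(-1/tau_i) / Z
        model = ExponentialMixtureModel((10.0, 1.0), (1.0, 10.0))
        s = sample_from_fitted(model, 10**5, seed=29)
        w_slow = (1.0 * 10.0 * np.exp(-0.1)) / (
            10.0 * 1.0 * np.exp(-1.0) + 1.0 * 10.0 * np.exp(-0.1))
        frac_above = (s.durations > 6.0).mean()
        # essentially all mass above 6 epochs comes from the tau=10 component
        expected = w_slow * np.exp(-5.0 / 10.0)
        assert abs(frac_above - expected) < 0.01


class TestReproducibility:
    def test_generators_bit_identical_under_seed(self):
        spec = MixtureSpec(((1.0, 100), (10.0, 50)))
        for maker in (
            lambda s: draw_power_law(500, 3.0, 1.0, s).durations,
            lambda s: draw_exponential_mixture(spec, s).durations,
            lambda s: simulate_markov_hypnogram(MarkovSpec(0.9, 0.9, 50), s)[0].durations,
        ):
            np.testing.assert_array_equal(maker(42), maker(42))
            assert not np.array_equal(maker(42), maker(43))


class TestQuotas:
    def test_fig2_style_quotas(self):
        assert quotas_from_proportions((0.474, 0.342, 0.184), 38000) == (
            18012, 12996, 6992)

    def test_vuong_experiment_quotas(self):
        assert quotas_from_proportions((4.0, 1.0, 0.5), 640) == (466, 116, 58)

    @given(
        weights=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=4),
        n=st.integers(1, 5000),
    )
    def test_quotas_sum_exactly(self, weights, n):
        q = quotas_from_proportions(weights, n)
        assert sum(q) == n
        assert all(v >= 0 for v in q)


def test_bout_sample_rejects_empty_and_non_finite():
    with pytest.raises(ValueError):
        BoutSample(np.array([]))
    with pytest.raises(ValueError):
        BoutSample(np.array([1.0, np.inf]))
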