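"""Histogram binning, power-law MLE, multi-exponential NLS, and log-log OLS."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from boutlaw import (
    BoutSample,
    DurationHistogram,
    ExponentialMixtureModel,
    MixtureSpec,
    bin_histogram,
    draw_exponential_mixture,
    draw_power_law,
    fit_exponentials_nls,
    fit_power_law_mle,
    fit_power_law_ols,
    normalize_to_pdf,
)
from boutlaw.model_fitting import DegenerateSampleError, FitError


class TestBinHistogram:
    def test_floor_rule_with_gap(self):
        hist = bin_histogram(BoutSample(np.array([1.2, 1.9, 3.0, 3.7])))
        np.testing.assert_array_equal(hist.bin_start, [1, 2, 3])
        np.testing.assert_array_equal(hist.counts, [2, 0, 2])

    @given(st.lists(st.floats(1.0, 500.0), min_size=1, max_size=200))
    def test_count_conservation(self, values):
        sample = BoutSample(np.array(values))
        assert bin_histogram(sample).total == sample.n

    def test_geometric_decay_of_binned_exponential(self):
        # adjacent bin counts of a truncated exponential decay by exp(-1/tau)
        s = draw_exponential_mixture(MixtureSpec(((5.0, 10**5),)), seed=3)
        counts = bin_histogram(s).counts
        target = np.exp(-1.0 / 5.0)
        for b in range(10):
            ratio = counts[b + 1] / counts[b]
            se = ratio * np.sqrt(1.0 / counts[b] + 1.0 / counts[b + 1])
            assert abs(ratio - target) < 3 * se

    def test_representative_modes(self):
        hist = DurationHistogram(np.array([2, 3]), np.array([1, 1]))
        np.testing.assert_array_equal(hist.representative("midpoint"), [2.5, 3.5])
        np.testing.assert_array_equal(hist.representative("left"), [2.0, 3.0])
        with pytest.raises(ValueError):
            hist.representative("right")


class TestPowerLawMle:
    def test_closed_form_small_sample(self):
        sample = BoutSample(np.array([1.0, 2.0, 4.0, 8.0]))
        model = fit_power_law_mle(sample)
        assert model.alpha == pytest.approx(1.0 + 4.0 / np.log(64.0), abs=1e-12)

    def test_matches_numeric_likelihood_maximisation(self, rng):
        # oracle: maximise the Pareto log-likelihood numerically
        for _ in range(20):
            x = (1.0 - rng.random(50)) ** (-1.0 / rng.uniform(0.8, 3.0))
            model = fit_power_law_mle(BoutSample(x))
            nll = lambda a: -(np.log(a - 1.0) - a * np.log(x).mean()) * x.size
            opt = minimize_scalar(nll, bounds=(1.0 + 1e-9, 50.0), method="bounded",
                                  options={"xatol": 1e-12})
            assert model.alpha == pytest.approx(opt.x, abs=1e-6)

    def test_parameter_recovery_at_large_n(self):
        s = draw_power_law(10**5, 3.0, 1.0, seed=19)
        assert fit_power_law_mle(s).alpha == pytest.approx(3.0, abs=0.02)

    def test_degenerate_sample_is_fit_failure(self):
        with pytest.raises(DegenerateSampleError):
            fit_power_law_mle(BoutSample(np.ones(10)))

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law_mle(BoutSample(np.array([1.0, 3.0])), x_min=2.0)


class TestExponentialNls:
    def test_exact_mono_exponential_recovery(self):
        # noiseless counts evaluated at the bin representatives
        bins = np.arange(1, 51)
        counts = 100.0 * np.exp(-(bins + 0.5) / 4.0)
        fit = fit_exponentials_nls(DurationHistogram(bins, counts), 1)
        assert fit.converged
        assert fit.model.amplitudes[0] == pytest.approx(100.0, rel=1e-4)
        assert fit.model.taus[0] == pytest.approx(4.0, rel=1e-4)

    def test_idempotence_on_own_predictions(self):
        model = ExponentialMixtureModel((80.0, 8.0), (1.5, 9.0))
        bins = np.arange(1, 61)
        counts = model.unnormalized(bins + 0.5)
        refit = fit_exponentials_nls(DurationHistogram(bins, counts), 2)
        assert refit.converged
        assert np.allclose(refit.model.taus, model.taus, rtol=1e-6)
        assert np.allclose(refit.model.amplitudes, model.amplitudes, rtol=1e-6)

    def test_mixture_parameter_recovery(self):
        spec = MixtureSpec(((1.0, 50000), (10.0, 50000)))
        s = draw_exponential_mixture(spec, seed=31)
        fit = fit_exponentials_nls(bin_histogram(s), 2, seed=31)
        assert fit.converged
        assert fit.model.taus[0] == pytest.approx(1.0, rel=0.1)
        assert fit.model.taus[1] == pytest.approx(10.0, rel=0.1)

    def test_returned_models_satisfy_positivity(self):
        # constraint screen: no returned model ever has a_i <= 0 or tau_i <= 0
        for i in range(30):
            s = draw_power_law(160, 3.0, 1.0, seed=1000 + i)
            for k in (1, 2, 3):
                fit = fit_exponentials_nls(bin_histogram(s), k, seed=i)
                if fit.converged:
                    assert all(a > 0 for a in fit.model.amplitudes)
                    assert all(t > 0 for t in fit.model.taus)
                else:
                    assert fit.model is None
                    assert fit.status in ("optimizer-failure",
                                          "constraint-violation")

    def test_canonical_tau_ordering(self):
        model = ExponentialMixtureModel((1.0, 2.0, 3.0), (20.0, 1.0, 5.0))
        assert model.taus == (1.0, 5.0, 20.0)
        assert model.amplitudes == (2.0, 3.0, 1.0)

    def test_invalid_k(self):
        hist = DurationHistogram(np.arange(1, 10), np.ones(9))
        with pytest.raises(ValueError):
            fit_exponentials_nls(hist, 4)

    def test_underdetermined_histogram_is_optimizer_failure(self):
        hist = DurationHistogram(np.array([1, 2, 3]), np.array([5, 2, 1]))
        assert fit_exponentials_nls(hist, 3).status == "optimizer-failure"

    def test_runaway_tau_screened(self):
        # a flat histogram wants tau -> infinity; that estimate is unidentifiable
        hist = DurationHistogram(np.arange(1, 30), np.full(29, 7.0))
        fit = fit_exponentials_nls(hist, 1)
        assert not fit.converged


class TestNormalizeToPdf:
    def test_unit_mono_exponential_closed_forms(self):
        dens = normalize_to_pdf(ExponentialMixtureModel((1.0,), (1.0,)))
        assert dens.normalization == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert dens.cdf(2.0) == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("amps,taus", [
        ((1.0,), (1.0,)),
        ((5.0, 1.0), (0.5, 20.0)),
        ((3.0, 2.0, 0.5), (1.0, 6.0, 60.0)),
    ])
    def test_cdf_axioms_and_quadrature(self, amps, taus):
        dens = normalize_to_pdf(ExponentialMixtureModel(amps, taus))
        assert dens.cdf(1.0) == 0.0
        assert dens.cdf(1e9) == pytest.approx(1.0, abs=1e-12)
        grid = np.linspace(1.0, 500.0, 400)
        assert np.all(np.diff(dens.cdf(grid)) >= 0)
        mass, _ = quad(dens.pdf, 1.0, 1e4, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_logpdf_matches_pdf(self):
        dens = normalize_to_pdf(ExponentialMixtureModel((2.0, 1.0), (1.0, 12.0)))
        x = np.array([1.0, 2.5, 40.0, 300.0])
        np.testing.assert_allclose(np.exp(dens.logpdf(x)), dens.pdf(x), rtol=1e-12)

    def test_full_support_normalisation(self):
        # support="full" treats the curve as a PDF over [0, inf)
        model = ExponentialMixtureModel((3.0, 0.5), (1.0, 10.0))
        dens = normalize_to_pdf(model, support="full")
        mass, _ = quad(dens.pdf, 0.0, 1e3, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-8)
        # full-support density is smaller on [1, inf) than the truncated one
        trunc = normalize_to_pdf(model)
        x = np.array([1.0, 3.0, 20.0])
        assert np.all(dens.pdf(x) < trunc.pdf(x))
        with pytest.raises(ValueError):
            normalize_to_pdf(model, support="half")


class TestPowerLawOls:
    def test_exact_log_linear_counts(self):
        # counts (2520/x)^3 are integers and exactly log-linear vs the left edge
        bins = np.arange(1, 11)
        counts = (2520 // bins) ** 3
        fit = fit_power_law_ols(DurationHistogram(bins, counts),
                                representative="left")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(-3.0, abs=1e-10)

    def test_three_exponential_mimicry_scores_high(self):
        spec = MixtureSpec.from_proportions((1.0, 6.0, 60.0),
                                            (0.474, 0.342, 0.184), 38000)
        s = draw_exponential_mixture(spec, seed=0)
        fit = fit_power_law_ols(bin_histogram(s))
        assert fit.r_squared > 0.9

    def test_mono_exponential_scores_materially_lower(self):
        mono = draw_exponential_mixture(MixtureSpec(((20.0, 10**4),)), seed=1)
        r2_mono = fit_power_law_ols(bin_histogram(mono)).r_squared
        spec = MixtureSpec.from_proportions((1.0, 6.0, 60.0),
                                            (0.474, 0.342, 0.184), 38000)
        mimic = draw_exponential_mixture(spec, seed=1)
        r2_mimic = fit_power_law_ols(bin_histogram(mimic)).r_squared
        assert r2_mono < r2_mimic - 0.05

    def test_too_few_positive_bins(self):
        hist = DurationHistogram(np.array([1, 2, 3]), np.array([4, 0, 2]))
        with pytest.raises(FitError):
            fit_power_law_ols(hist)
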