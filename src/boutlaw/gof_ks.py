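"""Parametric-bootstrap Kolmogorov-Smirnov goodness-of-fit testing.

The procedure, per tested sample:

1. fit the candidate family (power law by MLE, or a k-exponential mixture by
   constrained NLS on the unit-width histogram) to the sample;
2. compute the observed KS statistic d_o between the sample's empirical CDF
   and the fitted continuous CDF on [1, inf);
3. draw ``n_ref`` reference samples of the same size from the fitted model;
4. re-fit each reference sample to the same family and compute its statistic
   d_s against its *own* re-fitted CDF;
5. report p = (number of d_s >= d_o) / n_ref.

Asymptotic KS tables do not apply because the model is fitted to the data
being tested; the null distribution of d_o must be simulated.  The critical
value is 0.05, and the boundary case p = 0.05 counts as *not* rejected
(rejection requires p < 0.05).

Two KS distances are used, one per fitting route.  The power-law family is
fitted to raw durations, so its statistic is the classical continuous one
(:func:`ks_distance`, empirical CDF vs fitted CDF, both step sides).  The
exponential families are fitted to the unit-width histogram — the fitted
object is a probability mass function over duration bins — so their statistic
compares the cumulative floored-data histogram with the cumulative fitted bin
mass (:func:`ks_distance_binned`).  Reference samples receive exactly the
same treatment as the tested sample in each route.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .generators import SeedLike, draw_exponential_mixture, draw_power_law, seed_sequence
from .models import BoutSample, MixtureSpec, PowerLawModel
from .model_fitting import (
    DegenerateSampleError,
    ExpMixtureDensity,
    bin_histogram,
    fit_exponentials_nls,
    fit_power_law_mle,
    normalize_to_pdf,
)

__all__ = [
    "KSBootstrapResult",
    "MimicryResult",
    "NonConvergenceError",
    "ks_distance",
    "ks_distance_binned",
    "ks_bootstrap_p",
    "ks_bootstrap_for_expfit",
    "mimicry_probability",
]

# reference samples whose floored range would exceed this many unit bins are
# treated as failed draws (a degenerate fitted tau can make them astronomically
# long; re-binning them is neither meaningful nor affordable)
MAX_REF_BINS = 100_000

CRITICAL_P = 0.05
FAMILIES = ("powerlaw", "exp1", "exp2", "exp3")


class NonConvergenceError(RuntimeError):
    """The candidate-family fit to the test sample did not converge."""

    def __init__(self, status: str):
        super().__init__(f"fit did not converge: {status}")
        self.status = status


def ks_distance(sample: Union[BoutSample, np.ndarray], cdf: Callable) -> float:
    """Exact KS statistic between a sample's empirical CDF and a model CDF.

    d = max over the sorted sample of max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n),
    i.e. both sides of every empirical-CDF step are examined.
    """
    x = sample.durations if isinstance(sample, BoutSample) else np.asarray(sample, float)
    xs = np.sort(x)
    n = xs.size
    f = np.asarray(cdf(xs), dtype=float)
    i = np.arange(1, n + 1)
    return float(max((i / n - f).max(), (f - (i - 1) / n).max()))


def ks_distance_binned(
    sample: Union[BoutSample, np.ndarray], density: ExpMixtureDensity
) -> float:
    """KS statistic between the floored-data histogram and a fitted bin PMF.

    Both distributions are accumulated over unit-width bins b = 1..max:
    d = max_b | cum_hist(b)/n  -  G(b+1) |, where G is the fitted density's
    CDF on [1, inf), so G(b+1) is the fitted mass of bins 1..b.
    """
    x = sample.durations if isinstance(sample, BoutSample) else np.asarray(sample, float)
    floors = np.floor(x).astype(int)
    b_max = int(floors.max())
    cum_data = np.cumsum(np.bincount(floors, minlength=b_max + 1)[1:]) / x.size
    edges = np.arange(2, b_max + 2, dtype=float)
    cum_model = np.asarray(density.cdf(edges), dtype=float)
    return float(np.abs(cum_data - cum_model).max())


@dataclass(frozen=True)
class KSBootstrapResult:
    """Observed statistic, reference statistics, and the bootstrap p-value.

    ``d_s`` entries are in [0, 1] except for references whose re-fit never
    converged after the redraw budget; those are recorded as +inf, which
    counts toward p (conservative: pushes the test away from rejection).
    """

    d_o: float
    d_s: np.ndarray
    p_value: float
    fitted_model: object
    n_ref: int
    n_redraws: int = 0
    n_exhausted: int = 0

    @property
    def reject(self) -> bool:
        return self.p_value < CRITICAL_P


def _finish(d_o, d_s, model, n_ref, n_redraws=0, n_exhausted=0) -> KSBootstrapResult:
    d_s = np.asarray(d_s, dtype=float)
    p = float(np.mean(d_s >= d_o))
    return KSBootstrapResult(float(d_o), d_s, p, model, n_ref, n_redraws, n_exhausted)


def _powerlaw_refs(model: PowerLawModel, n: int, n_ref: int, rng) -> np.ndarray:
    """Reference d_s values for the power-law family, fully vectorised.

    Each row is a fresh sample from the fitted Pareto law; its exponent is
    re-estimated by the same closed-form MLE before the KS distance is taken.
    """
    u = rng.random((n_ref, n))
    xr = model.x_min * (1.0 - u) ** (-1.0 / (model.alpha - 1.0))
    alphas = 1.0 + n / np.log(xr / model.x_min).sum(axis=1)
    xs = np.sort(xr, axis=1)
    f = 1.0 - (xs / model.x_min) ** (1.0 - alphas[:, None])
    i = np.arange(1, n + 1)
    return np.maximum((i / n - f).max(axis=1), (f - (i - 1) / n).max(axis=1))


def ks_bootstrap_for_expfit(
    sample: BoutSample,
    density: ExpMixtureDensity,
    n_ref: int = 100,
    seed: SeedLike = 0,
    max_redraws: int = 10,
) -> KSBootstrapResult:
    """Bootstrap KS test given an already-fitted k-exponential density.

    Reference samples inherit the test sample's size and the >= 1 epoch
    support, and are floored and compared through :func:`ks_distance_binned`
    exactly as the tested sample is.  A reference whose re-fit fails
    (optimizer failure or positivity violation) is redrawn with a fresh child
    seed up to ``max_redraws`` times, after which its d_s is recorded as +inf.
    """
    k = density.model.k
    d_o = ks_distance_binned(sample, density)
    rng = np.random.default_rng(seed_sequence(seed))
    d_s = np.empty(n_ref)
    n_redraws = 0
    n_exhausted = 0
    for j in range(n_ref):
        value = np.inf
        for _ in range(max_redraws + 1):
            ref = density.sample(sample.n, rng)
            if ref.max() - ref.min() > MAX_REF_BINS:
                n_redraws += 1
                continue
            refit = fit_exponentials_nls(bin_histogram(BoutSample(ref)), k)
            if refit.converged:
                value = ks_distance_binned(ref, normalize_to_pdf(refit.model))
                break
            n_redraws += 1
        else:
            n_exhausted += 1
        d_s[j] = value
    return _finish(d_o, d_s, density.model, n_ref, n_redraws, n_exhausted)


def ks_bootstrap_p(
    sample: BoutSample,
    family: str,
    n_ref: int = 100,
    seed: SeedLike = 0,
) -> KSBootstrapResult:
    """Fit ``family`` to ``sample`` and run the full bootstrap KS test.

    ``family`` is ``"powerlaw"`` or ``"exp1" | "exp2" | "exp3"``.  Raises
    :class:`NonConvergenceError` when the candidate fit to the test sample
    itself fails (the caller decides how to count such iterations).
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    ss = seed_sequence(seed)
    fit_ss, boot_ss = ss.spawn(2)
    if family == "powerlaw":
        try:
            model = fit_power_law_mle(sample, x_min=1.0)
        except DegenerateSampleError as exc:
            raise NonConvergenceError("degenerate-mle") from exc
        d_o = ks_distance(sample, model.cdf)
        rng = np.random.default_rng(boot_ss)
        d_s = _powerlaw_refs(model, sample.n, n_ref, rng)
        return _finish(d_o, d_s, model, n_ref)
    k = int(family[3])
    fit = fit_exponentials_nls(bin_histogram(sample), k, seed=fit_ss)
    if not fit.converged:
        raise NonConvergenceError(fit.status)
    return ks_bootstrap_for_expfit(sample, normalize_to_pdf(fit.model), n_ref, boot_ss)


@dataclass(frozen=True)
class MimicryResult:
    """Fraction of iterations in which the candidate model survives the test.

    ``fraction_not_rejected`` uses the converged iterations as denominator
    (the convention of the published tables); ``fraction_all_iterations``
    divides by every iteration attempted, converged or not.
    """

    iterations: int
    n_converged: int
    n_not_rejected: int
    p_values: np.ndarray = field(repr=False)

    @property
    def fraction_not_rejected(self) -> float:
        if self.n_converged == 0:
            return float("nan")
        return self.n_not_rejected / self.n_converged

    @property
    def fraction_all_iterations(self) -> float:
        return self.n_not_rejected / self.iterations


def mimicry_probability(
    generator: Union[MixtureSpec, PowerLawModel],
    fit_family: str,
    n: Optional[int] = None,
    iterations: int = 1000,
    n_ref: int = 100,
    seed: int = 0,
    truncate_at_one: bool = True,
) -> MimicryResult:
    """Probability that repeated samples from ``generator`` survive ``fit_family``.

    Each iteration draws a fresh sample, runs the bootstrap KS test for the
    candidate family, and records whether p >= 0.05 (failure to reject).
    Iteration ``i`` uses child seeds ``SeedSequence([seed, i, 0])`` for the
    sample and ``SeedSequence([seed, i, 1])`` for the bootstrap, so individual
    iterations are reproducible in isolation and different drivers sharing a
    seed see identical samples.
    """
    if isinstance(generator, MixtureSpec):
        if n is not None and n != generator.n:
            raise ValueError("n is implied by the mixture spec's draw quotas")
        n = generator.n
    elif isinstance(generator, PowerLawModel):
        if n is None:
            raise ValueError("n is required for a power-law generator")
    else:
        raise TypeError("generator must be a MixtureSpec or PowerLawModel")

    seed = int(seed)
    p_values = np.full(iterations, np.nan)
    n_conv = 0
    n_keep = 0
    for i in range(iterations):
        sample_ss = np.random.SeedSequence([seed, i, 0])
        boot_ss = np.random.SeedSequence([seed, i, 1])
        if isinstance(generator, MixtureSpec):
            sample = draw_exponential_mixture(generator, sample_ss, truncate_at_one)
        else:
            sample = draw_power_law(n, generator.alpha, generator.x_min, sample_ss)
        try:
            res = ks_bootstrap_p(sample, fit_family, n_ref=n_ref, seed=boot_ss)
        except NonConvergenceError:
            continue
        p_values[i] = res.p_value
        n_conv += 1
        if not res.reject:
            n_keep += 1
    return MimicryResult(iterations, n_conv, n_keep, p_values)
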