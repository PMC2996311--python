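"""Histogram construction and the three fitting routines.

* continuous maximum-likelihood power-law fit with the lower threshold fixed
  at one epoch (no threshold scan),
* multi-exponential nonlinear least squares on the unit-width frequency
  histogram (Levenberg-Marquardt, zero offset, positivity screen),
* ordinary least squares power-law fit on the log-log histogram.

The exponential fitter deliberately mirrors routine practice in bout-duration
analysis rather than global optimisation: a single Levenberg-Marquardt pass
from conventional epoch-scale starting values (tau = 1, 5, 25 epochs),
iteration-capped at the customary NLS default of 50 iterations, whose
returned estimates are used as-is.  Only solutions violating the
decaying-function constraints (any amplitude or decay constant <= 0) are
discarded.  A globally optimal fit is *not* sought: the survival of a
candidate family under goodness-of-fit testing is a property of fits as they
are produced in the field's fitting workflow, and a globally optimised
mixture fit would answer a different (and, for the mimicry question, less
relevant) question.  Multi-start refinement remains available via
``max_starts`` for users who want the best attainable least-squares fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Optional

import numba
import numpy as np
from scipy.optimize import leastsq
from scipy.special import logsumexp

from .generators import SeedLike, seed_sequence
from .models import (
    BoutSample,
    DurationHistogram,
    ExponentialMixtureModel,
    OlsFit,
    PowerLawModel,
)

__all__ = [
    "FitError",
    "DegenerateSampleError",
    "ExpFitResult",
    "ExpMixtureDensity",
    "ExpMixtureFullDensity",
    "bin_histogram",
    "fit_power_law_mle",
    "fit_exponentials_nls",
    "normalize_to_pdf",
    "fit_power_law_ols",
]

# statuses reported by fit_exponentials_nls
CONVERGED = "converged"
OPTIMIZER_FAILURE = "optimizer-failure"
CONSTRAINT_VIOLATION = "constraint-violation"

# conventional starting decay constants (epochs): the canonical fast /
# intermediate / slow time scales of sleep-wake bout analysis
START_TAUS = {1: (1.0,), 2: (1.0, 5.0), 3: (1.0, 5.0, 25.0)}


class FitError(ValueError):
    """A fitting routine could not produce a valid model."""


class DegenerateSampleError(FitError):
    """Sample admits no finite parameter estimate (e.g. all durations equal x_min)."""


def bin_histogram(sample: BoutSample) -> DurationHistogram:
    """Floor-bin a sample into a unit-width frequency histogram.

    A duration x lands in bin floor(x); total counts equal the sample size.
    """
    floors = np.floor(sample.durations).astype(int)
    lo, hi = int(floors.min()), int(floors.max())
    counts = np.bincount(floors - lo, minlength=hi - lo + 1)
    return DurationHistogram(np.arange(lo, hi + 1), counts)


def fit_power_law_mle(sample: BoutSample, x_min: float = 1.0) -> PowerLawModel:
    """Continuous MLE of the scaling exponent with a fixed lower threshold.

    alpha_hat = 1 + n / sum(log(x_i / x_min)), applied to the raw (unbinned)
    durations.  Raises :class:`DegenerateSampleError` when every duration
    equals ``x_min`` (the estimate diverges).
    """
    x = sample.durations
    if np.any(x < x_min):
        raise ValueError("all durations must be >= x_min")
    s = float(np.log(x / x_min).sum())
    if s <= 0.0:
        raise DegenerateSampleError("all durations equal x_min; alpha diverges")
    return PowerLawModel(alpha=1.0 + x.size / s, x_min=x_min)


@dataclass(frozen=True)
class ExpFitResult:
    """Outcome of a multi-exponential NLS fit.

    ``status`` is one of ``"converged"``, ``"optimizer-failure"`` or
    ``"constraint-violation"``; ``model`` is populated only when the fit
    satisfies the positivity constraints.  ``raw_params`` keeps the raw
    estimate (a_1..a_k, tau_1..tau_k) for diagnostics even when discarded.
    """

    status: str
    model: Optional[ExponentialMixtureModel]
    k: int
    cost: float = np.nan
    n_starts: int = 0
    raw_params: Optional[tuple[float, ...]] = None

    @property
    def converged(self) -> bool:
        return self.status == CONVERGED


# The residual and Jacobian kernels are jitted: Levenberg-Marquardt evaluates
# them a few hundred times per fit and the bootstrap runs tens of thousands of
# fits per sweep cell.  The exponent is clipped so that trial steps with
# tau <= 0 (a growing exponential) produce huge finite residuals instead of
# overflow.
@numba.njit(cache=False)
def _mix_residual(params, x, y, k):
    m = x.size
    out = np.empty(m)
    for i in range(m):
        s = 0.0
        for j in range(k):
            z = -x[i] / params[k + j]
            if z > 50.0:
                z = 50.0
            elif z < -700.0:
                z = -700.0
            s += params[j] * np.exp(z)
        out[i] = s - y[i]
    return out


@numba.njit(cache=False)
def _mix_jacobian(params, x, y, k):
    m = x.size
    jac = np.empty((m, 2 * k))
    for i in range(m):
        for j in range(k):
            z = -x[i] / params[k + j]
            if z > 50.0:
                z = 50.0
            elif z < -700.0:
                z = -700.0
            e = np.exp(z)
            jac[i, j] = e
            v = params[j] / (params[k + j] * params[k + j]) * e * x[i]
            jac[i, j + k] = v if np.isfinite(v) else 0.0
    return jac


def fit_exponentials_nls(
    hist: DurationHistogram,
    k: int,
    seed: SeedLike = 0,
    max_starts: int = 1,
    max_nfev: int = 100,
    tau_max: float = 1000.0,
    representative: str = "midpoint",
) -> ExpFitResult:
    """Fit sum_i a_i exp(-x/tau_i) (zero offset) to a unit-width histogram.

    Unweighted Levenberg-Marquardt least squares (analytic Jacobian) on
    (bin representative, count) pairs, zero-count bins included.  Starting
    values: decay constants from :data:`START_TAUS` and an amplitude decade
    ladder max(count) * 10**-(i-1); the estimate returned after at most
    ``max_nfev`` residual evaluations is used as-is, stalled or not.  A
    histogram with fewer bins than free parameters, an optimizer exception,
    or non-finite estimates give ``"optimizer-failure"``; finite estimates
    with any amplitude or tau <= 0, or any tau above ``tau_max``, give
    ``"constraint-violation"``; otherwise the model is returned with
    components in ascending-tau order.  ``tau_max`` (default 1000 epochs,
    over eight hours of a single uninterrupted state) screens out
    unidentifiable runaway decay constants far beyond any observable bout
    duration; they arise occasionally when a stalled fit dumps a component
    onto the flat tail.

    ``max_starts > 1`` adds seed-jittered restarts (lognormal factor on the
    starting taus) that keep the lowest-cost constraint-satisfying solution —
    a better estimator, but not the default workflow emulated here.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    x = hist.representative(representative)
    y = np.asarray(hist.counts, dtype=float)
    if x.size < 2 * k:
        # fewer observations than free parameters: under-determined
        return ExpFitResult(OPTIMIZER_FAILURE, None, k)

    rng = np.random.default_rng(seed_sequence(seed))
    taus0 = np.asarray(START_TAUS[k])
    a0 = y.max() * 10.0 ** -np.arange(k)

    best = None  # (cost, params) among constraint-satisfying solutions
    last = None  # last finite estimate of any start (for status reporting)
    n_starts = 0
    for attempt in range(max(1, max_starts)):
        n_starts += 1
        t_init = taus0 if attempt == 0 else taus0 * rng.lognormal(0.0, 0.5, k)
        p0 = np.concatenate([a0, t_init])
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # maxfev-reached is expected
                p_hat, _ier = leastsq(
                    _mix_residual, p0, Dfun=_mix_jacobian, args=(x, y, k),
                    xtol=1.49e-8, ftol=1.49e-8, gtol=1e-15, maxfev=max_nfev,
                )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.all(np.isfinite(p_hat)):
            continue
        cost = 0.5 * float((_mix_residual(p_hat, x, y, k) ** 2).sum())
        last = (cost, tuple(float(v) for v in p_hat))
        a, tau = p_hat[:k], p_hat[k:]
        if np.all(a > 0.0) and np.all(tau > 0.0) and np.all(tau <= tau_max):
            if best is None or cost < best[0]:
                best = last
            if max_starts <= 1:
                break
    if best is not None:
        cost, params = best
        model = ExponentialMixtureModel(params[:k], params[k:])
        return ExpFitResult(CONVERGED, model, k, cost=cost,
                            n_starts=n_starts, raw_params=params)
    if last is not None:
        cost, params = last
        return ExpFitResult(CONSTRAINT_VIOLATION, None, k, cost=cost,
                            n_starts=n_starts, raw_params=params)
    return ExpFitResult(OPTIMIZER_FAILURE, None, k, n_starts=n_starts)


@dataclass(frozen=True)
class ExpMixtureDensity:
    """A fitted exponential mixture normalised to a density on [1, inf).

    g(x) = f(x) / Z with Z = sum_i a_i tau_i exp(-1/tau_i); equivalently a
    mixture of unit-shifted exponentials with weights
    w_i = a_i tau_i exp(-1/tau_i) / Z.  Closed-form CDF, bin masses and a
    sampler are used by the KS bootstrap.
    """

    model: ExponentialMixtureModel

    @cached_property
    def _parts(self) -> tuple[np.ndarray, np.ndarray, float]:
        a = np.asarray(self.model.amplitudes)
        tau = np.asarray(self.model.taus)
        mass = a * tau * np.exp(-1.0 / tau)
        z = float(mass.sum())
        return tau, mass / z, z

    @property
    def weights(self) -> np.ndarray:
        return self._parts[1]

    @property
    def normalization(self) -> float:
        """Z, the integral of the unnormalised curve over [1, inf)."""
        return self._parts[2]

    def pdf(self, x):
        tau, w, _ = self._parts
        x = np.asarray(x, dtype=float)
        dens = (w / tau * np.exp(-(x[..., None] - 1.0) / tau)).sum(axis=-1)
        out = np.where(x >= 1.0, dens, 0.0)
        return out if out.ndim else float(out)

    def logpdf(self, x):
        tau, w, _ = self._parts
        x = np.asarray(x, dtype=float)
        terms = np.log(w / tau) - (x[..., None] - 1.0) / tau
        out = np.where(x >= 1.0, logsumexp(terms, axis=-1), -np.inf)
        return out if out.ndim else float(out)

    def cdf(self, x):
        tau, w, _ = self._parts
        x = np.asarray(x, dtype=float)
        out = np.where(
            x >= 1.0,
            (w * (1.0 - np.exp(-(np.maximum(x[..., None], 1.0) - 1.0) / tau))).sum(axis=-1),
            0.0,
        )
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n draws: multinomial component counts, then 1 + Exponential(tau_i)."""
        tau, w, _ = self._parts
        counts = rng.multinomial(n, w)
        parts = [
            1.0 + rng.exponential(t, size=c) for t, c in zip(tau, counts) if c
        ]
        return np.concatenate(parts)


@dataclass(frozen=True)
class ExpMixtureFullDensity:
    """A fitted exponential mixture normalised over its full support [0, inf).

    The direct PDF normalisation of the fitted curve: g(x) = f(x) / sum_i
    a_i tau_i, a mixture of ordinary exponentials with weights
    w_i = a_i tau_i / sum_j a_j tau_j.  Unlike :class:`ExpMixtureDensity`, the
    mass below one epoch is *not* conditioned away, so evaluating bout data
    (all >= 1) under this density charges the model for its sub-epoch mass.
    Used by the model-choice experiment; see the methods note.
    """

    model: ExponentialMixtureModel

    @cached_property
    def _parts(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.model.amplitudes)
        tau = np.asarray(self.model.taus)
        mass = a * tau
        return tau, mass / mass.sum()

    def pdf(self, x):
        tau, w = self._parts
        x = np.asarray(x, dtype=float)
        dens = (w / tau * np.exp(-x[..., None] / tau)).sum(axis=-1)
        out = np.where(x >= 0.0, dens, 0.0)
        return out if out.ndim else float(out)

    def logpdf(self, x):
        tau, w = self._parts
        x = np.asarray(x, dtype=float)
        terms = np.log(w / tau) - x[..., None] / tau
        out = np.where(x >= 0.0, logsumexp(terms, axis=-1), -np.inf)
        return out if out.ndim else float(out)


def normalize_to_pdf(
    model: ExponentialMixtureModel, support: str = "truncated"
):
    """Normalise a fitted mixture curve to a probability density.

    ``support="truncated"`` (default) conditions the density on the
    observable bout range [1, inf) — the correct likelihood for data that
    only exist above one epoch, and the density the KS bootstrap samples
    from.  ``support="full"`` normalises the curve over [0, inf) instead,
    i.e. treats the fitted function directly as a PDF without conditioning.
    """
    if support == "truncated":
        return ExpMixtureDensity(model)
    if support == "full":
        return ExpMixtureFullDensity(model)
    raise ValueError(f"unknown support: {support!r}")


def fit_power_law_ols(
    hist: DurationHistogram, representative: str = "midpoint"
) -> OlsFit:
    """OLS of log(count) on log(duration) over positive-count bins.

    This is the log-log straight-line fit whose R-squared is often (mis)used
    as a power-law goodness-of-fit measure.  Requires at least three
    positive-count bins.
    """
    mask = hist.counts > 0
    if int(mask.sum()) < 3:
        raise FitError("need at least 3 positive-count bins for the log-log OLS fit")
    lx = np.log(hist.representative(representative)[mask])
    ly = np.log(np.asarray(hist.counts, dtype=float)[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    return OlsFit(float(slope), float(intercept), float(r2), int(mask.sum()))
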