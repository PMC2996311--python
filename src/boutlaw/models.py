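"""Core containers: bout samples, generator specifications, and candidate models.

All durations are expressed in units of one scoring epoch (30 s of clinical
polysomnography).  The two candidate families for bout-duration densities are

* a power law  f(x) = c x**(-alpha)  on [x_min, inf), and
* a sum of up to three decaying exponentials  f(x) = sum_i a_i exp(-x / tau_i)
  with zero vertical offset, restricted to x >= 1 once normalised.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "BoutSample",
    "MixtureSpec",
    "MarkovSpec",
    "PowerLawModel",
    "ExponentialMixtureModel",
    "DurationHistogram",
    "OlsFit",
    "quotas_from_proportions",
]


def quotas_from_proportions(weights: Sequence[float], n: int) -> tuple[int, ...]:
    """Split ``n`` draws among components by the largest-remainder method.

    Guarantees the integer quotas sum exactly to ``n``; ties in the fractional
    remainders are broken toward the earlier component.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    ideal = n * w / w.sum()
    base = np.floor(ideal).astype(int)
    short = n - int(base.sum())
    if short:
        # stable argsort: earlier components win remainder ties
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
    return tuple(int(q) for q in base)


@dataclass(frozen=True)
class BoutSample:
    """A finite collection of bout durations (epochs) with generator provenance.

    ``provenance`` records the generating family, its parameters and the seed,
    so any sample can be regenerated bit-for-bit.
    """

    durations: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.durations, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("durations must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("durations must be finite")
        object.__setattr__(self, "durations", arr)

    @property
    def n(self) -> int:
        return int(self.durations.size)

    def min(self) -> float:
        return float(self.durations.min())


@dataclass(frozen=True)
class MixtureSpec:
    """Specification of an exponential-mixture generator.

    Each component is a pair ``(tau, n_draws)``: the decay constant in epochs
    and the number of *accepted* draws (values >= 1 epoch) to take from it.
    Component proportions are therefore exact draw counts, not probabilities.
    """

    components: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(t), int(m)) for t, m in self.components)
        if not 1 <= len(comps) <= 3:
            raise ValueError("component count must be 1, 2 or 3")
        if any(t <= 0 for t, _ in comps):
            raise ValueError("all tau must be positive")
        if any(m < 0 for _, m in comps):
            raise ValueError("n_draws must be non-negative")
        if sum(m for _, m in comps) <= 0:
            raise ValueError("at least one component needs n_draws > 0")
        object.__setattr__(self, "components", comps)

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.components)

    @property
    def n_draws(self) -> tuple[int, ...]:
        return tuple(m for _, m in self.components)

    @property
    def n(self) -> int:
        return sum(self.n_draws)

    @classmethod
    def from_proportions(
        cls, taus: Sequence[float], proportions: Sequence[float], n: int
    ) -> "MixtureSpec":
        """Build a spec whose draw quotas realise ``proportions`` of ``n`` exactly."""
        if len(taus) != len(proportions):
            raise ValueError("taus and proportions must have equal length")
        quotas = quotas_from_proportions(proportions, n)
        return cls(tuple(zip((float(t) for t in taus), quotas)))


@dataclass(frozen=True)
class MarkovSpec:
    """Two-state (sleep/wake) first-order Markov chain at epoch resolution."""

    p_stay_sleep: float
    p_stay_wake: float
    n_bouts: int

    def __post_init__(self) -> None:
        for p in (self.p_stay_sleep, self.p_stay_wake):
            if not 0.0 < p < 1.0:
                raise ValueError("stay probabilities must lie strictly in (0, 1)")
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be positive")


@dataclass(frozen=True)
class PowerLawModel:
    """Pareto density f(x) = c x**(-alpha) on [x_min, inf).

    ``alpha`` is the scaling exponent (the magnitude of the log-log slope);
    the lower threshold ``x_min`` is fixed to one epoch throughout the
    simulation pipeline.  The normalisation c = (alpha-1) * x_min**(alpha-1).
    """

    alpha: float
    x_min: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 1.0:
            raise ValueError("alpha must exceed 1 for a normalizable density")
        if not self.x_min > 0.0:
            raise ValueError("x_min must be positive")

    @property
    def c(self) -> float:
        return (self.alpha - 1.0) * self.x_min ** (self.alpha - 1.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x >= self.x_min, self.c * x ** (-self.alpha), 0.0)
        return out if out.ndim else float(out)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                x >= self.x_min,
                math.log(self.alpha - 1.0)
                - math.log(self.x_min)
                - self.alpha * np.log(x / self.x_min),
                -np.inf,
            )
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(
            x >= self.x_min, 1.0 - (x / self.x_min) ** (1.0 - self.alpha), 0.0
        )
        return out if out.ndim else float(out)

    def ppf(self, q):
        """Inverse CDF: x = x_min * (1 - q)**(-1/(alpha-1))."""
        q = np.asarray(q, dtype=float)
        out = self.x_min * (1.0 - q) ** (-1.0 / (self.alpha - 1.0))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExponentialMixtureModel:
    """Sum of k in {1,2,3} decaying exponentials with zero offset.

    f(x) = sum_i a_i exp(-x / tau_i).  Amplitudes a_i are the y-intercepts of
    the components on the fitted frequency scale; tau_i are decay constants in
    epochs.  Both are required positive (models violating this are never
    constructed; the fitter reports them as constraint violations instead).
    Components are stored in ascending-tau order for comparability.
    """

    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    offset: float = 0.0  # fixed at zero by design

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.amplitudes)
        t = tuple(float(v) for v in self.taus)
        if len(a) != len(t) or not 1 <= len(t) <= 3:
            raise ValueError("need matching amplitudes/taus with 1-3 components")
        if any(not np.isfinite(v) or v <= 0 for v in a + t):
            raise ValueError("amplitudes and taus must be finite and positive")
        if self.offset != 0.0:
            raise ValueError("offset is fixed at zero")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "amplitudes", tuple(a[i] for i in order))
        object.__setattr__(self, "taus", tuple(t[i] for i in order))

    @property
    def k(self) -> int:
        return len(self.taus)

    def unnormalized(self, x):
        """Fitted frequency curve sum_i a_i exp(-x/tau_i) (counts scale)."""
        x = np.asarray(x, dtype=float)
        a = np.asarray(self.amplitudes)
        t = np.asarray(self.taus)
        out = (a * np.exp(-x[..., None] / t)).sum(axis=-1)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class DurationHistogram:
    """Unit-width (1 epoch) frequency histogram with floor binning.

    Bin ``i`` covers [bin_start_i, bin_start_i + 1); a duration x contributes
    to the bin floor(x).  Bins are contiguous from the smallest to the largest
    occupied floor, so zero-count interior bins are represented explicitly.
    Histograms built from samples have integer counts; real-valued counts are
    accepted so that noiseless model curves can be fitted directly.
    """

    bin_start: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bin_start, dtype=int)
        c = np.asarray(self.counts)
        if b.ndim != 1 or b.shape != c.shape or b.size == 0:
            raise ValueError("bin_start and counts must be matching 1-d arrays")
        c = c.astype(int) if np.issubdtype(c.dtype, np.integer) else c.astype(float)
        if np.any(np.diff(b) != 1):
            raise ValueError("bins must be contiguous with unit width")
        if np.any(c < 0) or not np.all(np.isfinite(c)) or np.any(b < 0):
            raise ValueError("bin starts and counts must be non-negative and finite")
        object.__setattr__(self, "bin_start", b)
        object.__setattr__(self, "counts", c)

    @property
    def total(self):
        """Sum of counts; equals the source sample size for binned samples."""
        return self.counts.sum()

    def representative(self, mode: str = "midpoint") -> np.ndarray:
        """x-coordinate used for each bin when fitting (midpoint by default)."""
        if mode == "midpoint":
            return self.bin_start + 0.5
        if mode == "left":
            return self.bin_start.astype(float)
        raise ValueError(f"unknown bin representative mode: {mode!r}")


@dataclass(frozen=True)
class OlsFit:
    """Ordinary least squares fit of log(count) on log(duration)."""

    slope: float
    intercept: float
    r_squared: float
    n_bins_used: int
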