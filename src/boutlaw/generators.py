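"""Random bout-duration generators.

Three generating families are provided: a Pareto power law, mixtures of
exponentials with per-component accepted-draw quotas, and a two-state Markov
hypnogram.  All generators share the >= 1 epoch truncation rule (values below
one scoring epoch are rejected and redrawn) and are reproducible from a seed.

Seed handling
-------------
Every function accepts either a plain integer or a ``numpy.random.SeedSequence``.
Drivers derive per-task child seeds as ``SeedSequence([master, index, ...])``,
so any cell / iteration of a sweep can be regenerated in isolation.
"""
from __future__ import annotations

from typing import Union

import numpy as np

from .models import BoutSample, MarkovSpec, MixtureSpec, PowerLawModel

SeedLike = Union[int, np.random.SeedSequence]

__all__ = [
    "draw_power_law",
    "draw_exponential_mixture",
    "simulate_markov_hypnogram",
    "sample_from_fitted",
    "seed_sequence",
    "cell_seed",
]


def seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    """Normalise an int (or SeedSequence) to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def cell_seed(master_seed: int, index: int) -> int:
    """Derive a compact integer child seed for sweep cell ``index``.

    Defined as the first state word of ``SeedSequence([master_seed, index])``
    reduced below 2**31, so a cell recorded in a results file can be re-run
    standalone from its stored seed.
    """
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)
    return int(state[0] % (2**31))


def draw_power_law(
    n: int, alpha: float, x_min: float = 1.0, seed: SeedLike = 0
) -> BoutSample:
    """Draw ``n`` i.i.d. bout durations from f(x) ~ x**(-alpha) on [x_min, inf).

    Uses the inverse CDF  x = x_min * (1-u)**(-1/(alpha-1)).  Requires
    alpha > 1 (the density is non-normalizable otherwise).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not alpha > 1.0:
        raise ValueError("alpha must exceed 1 (non-normalizable density)")
    ss = seed_sequence(seed)
    rng = np.random.default_rng(ss)
    model = PowerLawModel(alpha=alpha, x_min=x_min)
    x = model.ppf(rng.random(n))
    prov = {"family": "powerlaw", "alpha": alpha, "x_min": x_min,
            "seed": ss.entropy, "n": n}
    return BoutSample(np.atleast_1d(x), prov)


def _draw_truncated_exponential(
    rng: np.random.Generator, tau: float, n: int, truncate_at_one: bool
) -> np.ndarray:
    """Accepted draws from Exponential(mean tau); values < 1 epoch rejected."""
    if n == 0:
        return np.empty(0)
    if not truncate_at_one:
        return rng.exponential(tau, size=n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        batch = rng.exponential(tau, size=n - filled)
        keep = batch[batch >= 1.0]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def draw_exponential_mixture(
    spec: MixtureSpec, seed: SeedLike = 0, truncate_at_one: bool = True
) -> BoutSample:
    """Draw the exact per-component accepted quotas given by ``spec``.

    Each component contributes exactly ``n_draws`` values; any draw below one
    epoch is rejected and redrawn (so quotas count accepted draws only, and
    the conditional law of each component is a unit-shifted exponential).
    Components with a zero quota consume no random numbers, which makes the
    degenerate single-component edges of a sweep bit-identical to an explicit
    mono-exponential run under the same seed.
    """
    ss = seed_sequence(seed)
    rng = np.random.default_rng(ss)
    parts = [
        _draw_truncated_exponential(rng, tau, m, truncate_at_one)
        for tau, m in spec.components
    ]
    durations = np.concatenate([p for p in parts if p.size]) if spec.n else None
    prov = {
        "family": "expmix",
        "taus": spec.taus,
        "n_draws": spec.n_draws,
        "truncate_at_one": truncate_at_one,
        "seed": ss.entropy,
    }
    return BoutSample(durations, prov)


def simulate_markov_hypnogram(
    spec: MarkovSpec, seed: SeedLike = 0
) -> tuple[BoutSample, BoutSample]:
    """Bout durations from a two-state (sleep/wake) epoch-resolution chain.

    A run of a state with per-epoch stay probability p has the geometric
    dwell-time law P(L = k) = (1-p) p**(k-1), mean 1/(1-p); the chain is
    simulated directly as alternating geometric run lengths.  Returns
    ``spec.n_bouts`` sleep bouts and the same number of wake bouts, as
    integer-valued durations >= 1 epoch.
    """
    ss = seed_sequence(seed)
    rng = np.random.default_rng(ss)
    sleep = rng.geometric(1.0 - spec.p_stay_sleep, size=spec.n_bouts).astype(float)
    wake = rng.geometric(1.0 - spec.p_stay_wake, size=spec.n_bouts).astype(float)
    base = {"family": "markov", "p_stay_sleep": spec.p_stay_sleep,
            "p_stay_wake": spec.p_stay_wake, "seed": ss.entropy}
    return (
        BoutSample(sleep, {**base, "state": "sleep"}),
        BoutSample(wake, {**base, "state": "wake"}),
    )


def sample_from_fitted(model, n: int, seed: SeedLike = 0) -> BoutSample:
    """Draw ``n`` durations from a fitted model's density restricted to [1, inf).

    For a power law this is the same inverse-CDF sampler as
    :func:`draw_power_law`.  For an exponential mixture, a component i is
    chosen with probability  a_i tau_i exp(-1/tau_i) / Z  and the value drawn
    as 1 + Exponential(tau_i) (the exact law of the component conditioned on
    exceeding one epoch).
    """
    from .model_fitting import normalize_to_pdf  # local import; no cycle at import time

    if n < 1:
        raise ValueError("n must be at least 1")
    ss = seed_sequence(seed)
    rng = np.random.default_rng(ss)
    if isinstance(model, PowerLawModel):
        x = model.ppf(rng.random(n))
        prov = {"family": "powerlaw-fitted", "alpha": model.alpha,
                "x_min": model.x_min, "seed": ss.entropy}
        return BoutSample(np.atleast_1d(x), prov)
    density = normalize_to_pdf(model) if not hasattr(model, "sample") else model
    x = density.sample(n, rng)
    prov = {"family": "expmix-fitted", "taus": density.model.taus,
            "weights": tuple(density.weights), "seed": ss.entropy}
    return BoutSample(x, prov)
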