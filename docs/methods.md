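# Methods

`boutlaw` studies a statistical identifiability problem in sleep-wake
architecture: the distribution of bout durations (uninterrupted runs of sleep
or wake, measured in 30-second epochs) is routinely classified as either a
power law, f(x) = c·x^(−α) on [x_min, ∞), or a sum of up to three decaying
exponentials, f(x) = Σᵢ aᵢ·e^(−x/τᵢ) with zero offset.  The two families are
mechanistically loaded — scale-free self-organisation versus constant-rate
(Markovian) state switching — yet over wide regions of parameter space they
mimic one another at clinically realistic sample sizes (tens to hundreds of
bouts per subject).  The toolkit quantifies that mimicry by simulation.

## Generators

All durations are continuous, in epoch units, with the convention that draws
below one epoch (the shortest scoreable state) are rejected and redrawn.
Rejection with a fixed accepted-draw quota per component — rather than
truncating a fixed batch — keeps mixture compositions exact: a
`MixtureSpec` lists (τᵢ, nᵢ) pairs and each component contributes exactly nᵢ
accepted draws.  Because an exponential is memoryless, the accepted draws of
a component follow 1 + Exponential(τ) exactly; the power-law generator uses
the inverse CDF x = x_min(1−u)^(−1/(α−1)) and is unaffected by truncation at
x_min = 1.  The truncation switch `truncate_at_one` exists because the rule
is conventionally tied to the scoring epoch, not to the mathematics; it is on
by default for every family.  Components with a zero quota consume no random
numbers, so the degenerate edges of a proportion sweep are bit-identical to
explicit single-exponential runs under the same seed.

The two-state Markov hypnogram is simulated as alternating geometric dwell
times (P(L=k) = (1−p)p^(k−1) for stay-probability p), which is exactly the
run-length law of the epoch-resolution chain; bouts are integer-valued and
≥ 1 by construction.  The stay probabilities default to 0.9 per epoch (mean
bout 10 epochs = 5 minutes, a realistic fragmented-sleep scale) and are
configurable.

Seeds: every entry point takes one integer (or `numpy.random.SeedSequence`).
Drivers derive child seeds as `SeedSequence([seed, index, ...])`; a sweep
cell's integer seed is recorded in its output row, so any cell can be re-run
in isolation, and two drivers sharing a master seed see identical simulated
samples (this is how the KS and OLS sweeps score the same data).

## Fitting

**Power law.**  Continuous maximum likelihood on the raw durations with the
threshold fixed at one epoch: α̂ = 1 + n/Σln(xᵢ/x_min).  No threshold scan is
performed — scanning x_min on simulated bouts discards most of the sample
and makes fits incomparable across the parameter space.  A sample with all
durations at x_min has a divergent estimate and is reported as a failure.

**Multi-exponential.**  Unweighted Levenberg–Marquardt least squares of
Σ aᵢe^(−x/τᵢ) against the unit-width floor-binned frequency histogram
(bin representative: midpoint, configurable to the left edge; zero-count
bins included, since a zero count is informative for least squares; constant
bin widths are deliberately conservative toward the exponential family
because isolated long-duration events keep their full weight).  The offset
is fixed at zero — there is no biological basis for a constant floor of
arbitrarily long bouts — and fits are screened afterwards: any amplitude or
decay constant ≤ 0, or a decay constant above `tau_max` (default 1000
epochs, over eight hours of one uninterrupted state — far beyond any
observable bout and symptomatic of an unidentifiable runaway component), is
discarded as a constraint violation rather than projected back.

The default optimiser configuration is deliberately *not* a global
optimiser.  It performs a single LM pass (MINPACK `lmder`, analytic
Jacobian) from fixed conventional starting values — decay constants 1, 5
and 25 epochs, the canonical fast/intermediate/slow time scales of bout
analysis, and an amplitude decade ladder max(count)·10^(1−i) — capped at the
customary NLS default of 50 iterations, and uses the returned estimate
whether or not the optimiser reports convergence.  The rationale: the
question the toolkit answers is whether the *wrong family, as fitted in
standard practice*, survives goodness-of-fit testing.  Routine NLS fitting
stops at local, sometimes stalled, solutions; those are the fits whose
mimicry matters.  A globally optimised mixture fit (available via
`max_starts > 1`, which adds seed-jittered restarts and keeps the best
constraint-satisfying solution) is so flexible that at n = 640 a two- or
three-exponential fit to power-law data becomes essentially undetectable by
any goodness-of-fit test — true, but a statement about the best attainable
fit rather than about fits as practised.  Both behaviours are exposed; the
default reproduces the workflow-level question.

Fitted mixtures are normalised to densities on [1, ∞):
Z = Σ aᵢτᵢe^(−1/τᵢ), component weights wᵢ = aᵢτᵢe^(−1/τᵢ)/Z, with closed-form
CDF and sampler (choose component ∝ wᵢ, then 1 + Exponential(τᵢ)).

**Log-log OLS.**  Ordinary least squares of ln(count) on ln(duration) over
positive-count bins only (the log of zero is undefined), at least three bins
required.  Its R² is computed precisely because it is *not* a valid
goodness-of-fit measure for this problem; the OLS sweep demonstrates that.

## Parametric-bootstrap KS test

For a sample of size n and a candidate family: fit; compute the observed
statistic d_o; draw 100 reference samples of size n from the fitted model;
re-fit each reference to the same family; compute each reference's d_s
against its own re-fit; p = #(d_s ≥ d_o)/100.  The re-fit step is essential:
fitted models hug their data, so d_o must be compared with distances that
have the same optimism.  The critical value is 0.05, and the boundary
p = 0.05 counts as a failure to reject (p-values are multiples of 1/n_ref,
so the tie is reachable).  Asymptotic KS tables never apply because the
null model is estimated.

Two distances, one per fitting route.  The power-law route fits raw
durations, so d is the classical continuous statistic
max over sorted xᵢ of max(i/n − F(x₍ᵢ₎), F(x₍ᵢ₎) − (i−1)/n).  The
exponential route fits a histogram — the fitted object is a probability
mass function over duration bins — so d compares the cumulative floored-data
histogram with the cumulative fitted bin mass, max_b |Ĥ(b) − G(b+1)|.
Reference samples receive exactly the treatment of the tested sample in
each route.  A reference whose re-fit fails is redrawn (fresh child seed, up
to 10 times) and then recorded as d_s = +∞, which counts toward p and is
therefore conservative toward non-rejection; references whose floored range
would exceed 10⁵ unit bins (possible only under a degenerate fitted model)
count as failed draws.

`mimicry_probability` repeats the whole procedure over fresh samples and
reports the fraction with p ≥ 0.05 both among the iterations whose candidate
fit converged (the convention of the tabulated results) and among all
iterations.

## Vuong's model-choice test

Given two candidate densities normalised on [1, ∞), the pointwise
log-likelihood ratio ℓᵢ = ln f_A(xᵢ) − ln f_B(xᵢ) gives the summed ratio
LLR, the studentised statistic LLR/(σ̂√n) with σ̂ the sample SD of the ℓᵢ,
and a two-sided normal p-value.  For a fitted mixture, the NLS amplitudes
are converted to mixture weights (the fit defines the distribution; the
likelihood is not re-maximised).  Two verdict conventions circulate — raw
sign of LLR, and sign plus significance at 0.05 — and results report both;
`winner` uses sign + significance.  Zero variance of the ℓᵢ (identical
densities) is reported as undecided.

The replicated model-choice experiment (`run_vuong_experiment`, a
three-exponential mimicry generator with τ = 1/5/25, draws 4:1:0.5,
n = 640) exposes a support convention that the verdict hinges on.  Treating
the fitted decay curve directly as a PDF over [0, ∞) — the straightforward
reading of "normalise the fitted function" — charges the mixture for its
sub-epoch mass (a factor of up to e^(−1/τ) per component, crippling for the
dominant τ = 1 phase), and the *incorrect* power law then wins in
essentially every replicate.  Conditioning the mixture on the observable
range [1, ∞) instead — the statistically proper likelihood for data that
only exist above one epoch — largely reverses the verdict.  The experiment
defaults to the full-support convention because that is how a fitted
frequency curve is most often plugged into a likelihood in practice, and
the failure it produces is the cautionary result; the truncated convention
is a keyword away (`mixture_support="truncated"`).

## Sweep drivers and problem sizes

The landscape drivers map the probability of failing to reject a power-law
fit over two-exponential grids (fast τ₁ = 1, slow τ₂ ∈ {2..60}, fast-draw
proportion 0..1 in steps of 0.1), three-exponential proportion grids
(τ = 1/5/25 fixed, draw-count ratios 0.25–16 log-spaced) and
three-exponential τ grids (equal 1:1:1 draws, τ₂ and τ₃ varied, cells with
τ₂ > τ₃ skipped under the ascending-τ convention).  Draw-count quotas are
realised exactly by largest-remainder rounding.  Default grids are
desk-scale; per-cell iterations default to 1000 with the bundled acceptance
runs using 200–500, which puts Monte-Carlo standard errors at 0.01–0.035 on
a fraction — the sizes were chosen so a full grid runs in minutes on one
core.  Sweeps stream per-cell rows to CSV and can resume without recomputing
finished cells.

The packaged acceptance script (`scripts/acceptance.py`) recomputes the
exponential-fit grid at 500 iterations × 100 references per cell and the
Vuong experiment at 1000 replicates.

## What the generators do and do not emulate

Synthetic bouts are i.i.d. draws from clean parametric families.  Real
hypnogram data additionally carry scorer disagreement on brief arousals,
night-to-night nonstationarity, inter-subject heterogeneity when records are
pooled, and serial dependence between consecutive bouts.  Passing tests
therefore demonstrate properties of the estimators and tests under the
stated families — mimicry zones, test size, parameter recovery — not that
any particular empirical bout distribution is exponential or power-law.

## Known limitations

* The discrete (zeta) power-law MLE is out of scope; durations are treated
  as continuous and binned only for exponential fitting and display.
* Non-convergence statistics of the default NLS emulation depend on the
  fixed starting values; a different fitting culture (different starts,
  different iteration caps) shifts which samples count as converged, and
  with them the converged-subset fractions.  This sensitivity is intrinsic
  to convergence-conditioned reporting, which is why both denominators are
  always reported.
* Bootstrap p-values have granularity 1/n_ref; with the default 100
  references, a true p near 0.05 is resolved only to ±0.01.
* No weighted or Poisson-likelihood histogram fitting, and no
  stretched-exponential or log-normal alternatives.
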