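"""Draw a two-exponential bout sample and fit both candidate families.

A night of fragmented sleep might produce ~160 bouts whose durations mix a
fast (tau = 1 epoch) and a slow (tau = 15 epochs) transition process.  We fit
the (correct) two-exponential model to the unit-width histogram and the
(incorrect) power law by maximum likelihood, and print both.
"""
import numpy as np

from boutlaw import (
    MixtureSpec,
    bin_histogram,
    draw_exponential_mixture,
    fit_exponentials_nls,
    fit_power_law_mle,
)

spec = MixtureSpec(((1.0, 120), (15.0, 40)))
sample = draw_exponential_mixture(spec, seed=1)
print(f"sample: n = {sample.n}, mean = {sample.durations.mean():.2f} epochs, "
      f"max = {sample.durations.max():.1f}")

fit = fit_exponentials_nls(bin_histogram(sample), k=2, seed=1)
if fit.converged:
    taus = ", ".join(f"{t:.2f}" for t in fit.model.taus)
    amps = ", ".join(f"{a:.1f}" for a in fit.model.amplitudes)
    print(f"two-exponential fit: taus = ({taus}) epochs, amplitudes = ({amps})")
else:
    print(f"two-exponential fit did not converge: {fit.status}")

power_law = fit_power_law_mle(sample)
print(f"power-law MLE: alpha = {power_law.alpha:.3f} (threshold fixed at 1 epoch)")
print("The fitted taus recover the generating time scales; alpha is what a "
      "scale-free analysis would report for the same data.")
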