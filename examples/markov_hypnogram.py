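"""Two-state Markov sleep-wake chain and its mono-exponential bout law.

Fixed per-epoch stay probabilities generate geometrically distributed bout
durations -- the discrete analogue of a single exponential.  This is the
simplest null model of sleep fragmentation.
"""
import numpy as np

from boutlaw import MarkovSpec, bin_histogram, simulate_markov_hypnogram

spec = MarkovSpec(p_stay_sleep=0.9, p_stay_wake=0.9, n_bouts=4000)
sleep, wake = simulate_markov_hypnogram(spec, seed=5)

print(f"sleep bouts: n = {sleep.n}, mean = {sleep.durations.mean():.2f} epochs "
      f"(theory: 1/(1-0.9) = 10)")
hist = bin_histogram(sleep)
head = hist.counts[:5]
ratios = head[1:] / head[:-1]
print(f"first bins: {[int(c) for c in head]}; count ratios {np.round(ratios, 3)} "
      f"(theory: p_stay = 0.9)")
print("Successive histogram bins decay by a constant factor -- a straight "
      "line on a semi-log plot, the mono-exponential signature.")
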