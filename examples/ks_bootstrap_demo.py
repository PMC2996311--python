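"""Parametric-bootstrap KS goodness-of-fit test on a single sample.

Is a power law an acceptable description of data that really came from two
exponential processes?  The bootstrap builds the null distribution of the KS
statistic by refitting 100 reference samples drawn from the fitted model.
"""
from boutlaw import MixtureSpec, draw_exponential_mixture, ks_bootstrap_p

# a zone-of-mimicry configuration: fast tau=1 (75%), slow tau=15 (25%), n=40
spec = MixtureSpec(((1.0, 30), (15.0, 10)))
sample = draw_exponential_mixture(spec, seed=7)

res = ks_bootstrap_p(sample, "powerlaw", n_ref=100, seed=7)
print(f"observed KS statistic d_o = {res.d_o:.4f}")
print(f"reference d_s: min {res.d_s.min():.4f}, median "
      f"{sorted(res.d_s)[50]:.4f}, max {res.d_s.max():.4f}")
print(f"bootstrap p = {res.p_value:.2f} -> "
      f"{'reject' if res.reject else 'fail to reject'} the power law at 0.05")
print("With only 40 bouts the incorrect power law typically survives the "
      "test; the same configuration at n = 640 is rejected nearly always.")
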