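"""Round trip: simulate counts from the multilocus model, re-estimate.

Draws per-locus (Ps, Pn, Ds, Dn) from the exact Poisson means of the
multilocus likelihood with known class alphas, refits the class model,
and compares estimates with the generating truth - the core validation
that the estimator recovers what the generator planted.
"""

import numpy as np

from mkpop import SimConfig, fit_model, simulate_counts

cfg = SimConfig(n_loci=200, alpha_by_class=(-0.27, 0.33), seed=7)
truth = dict(zip(("nonimmune", "immune"), cfg.alpha_by_class))

print("sim  alpha_nonimmune  alpha_immune")
est = []
for s in range(5):
    data = simulate_counts(SimConfig(**{**cfg.__dict__, "seed": 100 + s}))
    fit = fit_model(data, "M3", seed=s)
    ab = fit.params.alpha_by_class
    est.append([ab["nonimmune"], ab["immune"]])
    print(f"{s:>3}  {ab['nonimmune']:>+15.3f}  {ab['immune']:>+12.3f}")

mean = np.mean(est, axis=0)
print(f"\ntruth: nonimmune {truth['nonimmune']:+.2f}, immune {truth['immune']:+.2f}")
print(f"mean estimate over 5 simulations: {mean[0]:+.3f}, {mean[1]:+.3f}")
print("Estimates scatter around the generating values; systematic bias is "
      "bounded in the test suite (|bias| <= 0.05 over 100 simulations).")
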