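"""Multilocus estimate of adaptive protein divergence by gene class.

Fits the four nested Poisson models (alpha = 0 / shared / per-locus /
per-class) to the 47 loci retained for the multilocus analysis, compares
them by likelihood ratio and AICc, and quantifies uncertainty in the
class-level alpha with a within-class bootstrap and a label-permutation
test.  Equal per-locus weights mirror the original count-only analysis.
"""

from mkpop import (
    bootstrap_class_alpha,
    compare_models,
    datasets,
    fit_model,
    permutation_class_test,
)

records = datasets.load_locus_records(multilocus_only=True)
print(f"{len(records)} loci "
      f"({sum(r.gene_class == 'immune' for r in records)} immune, "
      f"{sum(r.gene_class == 'nonimmune' for r in records)} non-immune)\n")

fits = [
    fit_model(records, m, seed=1, sample_size_weights=False)
    for m in ("M0", "M1", "M2", "M3")
]
print(compare_models(fits).round(4).to_string(index=False))

m3 = fits[3]
print("\nClass-level alpha (M3), 95% bootstrap intervals (1000 reps):")
for cls in ("nonimmune", "immune"):
    lo, hi = bootstrap_class_alpha(
        records, cls, reps=1000, seed=1, sample_size_weights=False
    )
    print(f"  {cls:<10} alpha = {m3.params.alpha_by_class[cls]:+.3f}  "
          f"({lo:+.3f}, {hi:+.3f})")

p = permutation_class_test(records, reps=999, seed=1, sample_size_weights=False)
print(f"\nPermutation test of |alpha_immune - alpha_nonimmune|: p = {p:.3f}")
print("A positive immune-class alpha with the class model (M3) favoured by "
      "AICc indicates\nmore adaptive protein divergence in immune genes.")
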