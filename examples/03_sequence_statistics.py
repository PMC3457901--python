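"""Per-locus sequence statistics on a simulated codon alignment.

Plants known numbers of synonymous/nonsynonymous polymorphisms and fixed
differences into a phased two-species alignment, then computes the
statistics the sequence pipeline reports: nucleotide diversity (pi_s,
pi_a), Jukes-Cantor-corrected divergence (K_s, K_a), the MK table, and
Tajima's D with its coalescent p-value.
"""

from mkpop import (
    PlantedCounts,
    SimConfig,
    build_mk_table,
    filter_low_frequency_variants,
    locus_summary,
    simulate_alignment,
)

cfg = SimConfig(sample_sizes=(12, 3), length_range=(600, 600), seed=42)
planted = PlantedCounts(Ps=6, Pn=2, Ds=5, Dn=3, carriers=(6, 6, 6, 1, 3, 6, 6, 2))
aln = simulate_alignment(cfg, planted, locus_id="demo")
print(f"alignment: {len(aln.ingroup_haplotypes)} ingroup + "
      f"{len(aln.outgroup_haplotypes)} outgroup haplotypes, {aln.n_codons} codons")

mk = build_mk_table(aln)
print(f"\nMK table before the 10% frequency filter: "
      f"Pn={mk.Pn:.0f} Ps={mk.Ps:.0f} Dn={mk.Dn:.0f} Ds={mk.Ds:.0f} "
      f"(planted {planted.Pn}, {planted.Ps}, {planted.Dn}, {planted.Ds})")

filtered = filter_low_frequency_variants(aln, threshold=0.10)
mk_f = build_mk_table(filtered)
print(f"after filtering variants below 10% frequency:   "
      f"Pn={mk_f.Pn:.0f} Ps={mk_f.Ps:.0f} Dn={mk_f.Dn:.0f} Ds={mk_f.Ds:.0f} "
      "(the 1/12-carrier variant is masked)")

summary, taj = locus_summary(filtered, coalescent_reps=5000, seed=7)
print(f"\npi_s = {summary.pi_s:.4f}  pi_a = {summary.pi_a:.4f}  "
      f"K_s = {summary.K_s:.4f}  K_a = {summary.K_a:.4f}")
print(f"Tajima's D (synonymous sites) = {taj.D:.3f}, "
      f"one-tailed coalescent p = {taj.p:.2f} "
      f"(n = {taj.n}, S = {taj.S})")
print("\nThe positive D reflects the planted intermediate-frequency variants "
      "(6 of 12 carriers);\nan excess of mid-frequency alleles is the signature "
      "balancing selection would leave.")
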