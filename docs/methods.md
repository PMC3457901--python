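# Methods

## Data model

A locus is a codon alignment of phased haplotypes from two species: an
ingroup population sample (≥ 2 haplotypes for polymorphism statistics)
and an outgroup sample (≥ 1 haplotype). Phasing is assumed done
upstream; the alphabet is A/C/G/T/N/`-` with no ambiguity codes. Codon
columns containing a gap, an N or a stop codon in *any* haplotype are
excluded for all haplotypes (complete deletion), so every statistic of a
locus sees the same site exposures. Analyses can start either from
alignments (FASTA + manifest) or from pre-tabulated per-locus counts
(P_n, P_s per species, D_n, D_s, length, sample sizes).

## Low-frequency variant filter

Mildly deleterious alleles segregating at low frequency depress α
estimates, so before all analyses any variant state whose relative
frequency among ingroup haplotypes is strictly below a threshold
(default 0.10) is replaced by the ingroup major state (ties broken
alphabetically). Interpreting the filter at the level of site variants
rather than whole haplotypes keeps sample sizes and site exposures
unchanged, which is what the per-locus haplotype counts of the bundled
dataset require. The filter applies to the ingroup only, is idempotent,
and can only reduce the number of segregating sites. Exact-threshold
frequencies are kept (the rule is "< threshold", not "≤").

## Site counting and per-locus statistics

Synonymous/nonsynonymous site exposures (L_s, L_n) and difference counts
follow Nei & Gojobori (1986): each codon's nine single-base changes are
classified against the standard genetic code (changes creating a stop
count as nonsynonymous, so L_s + L_n = 3 per codon exactly); codon pairs
differing at k positions are averaged over the k! mutational pathways
with equal weights, excluding pathways through stop codons unless all
pathways are excluded. Exposures are averaged over ingroup haplotypes.

π_s and π_a are average pairwise differences over ingroup haplotype
pairs divided by L_s and L_n. K_s and K_a average over all
ingroup × outgroup pairs and are Jukes–Cantor corrected
(K = −(3/4) ln(1 − 4p/3)); raw proportions ≥ 3/4 are reported missing
with a warning. Watterson's θ is S/(L·a(n)) with a(n) = Σ_{i<n} 1/i.

Tajima's D is computed at synonymous sites (total π and S, not
per-site) whenever the ingroup has ≥ 3 haplotypes; at n = 3 the
variance coefficients vanish and π ≡ S/a(n), so D is defined as 0.
Significance is one-tailed in the direction of the observed sign,
against neutral coalescent genealogies (Kingman pair-merging with
exponential waiting times) onto which exactly S mutations are dropped
with probability proportional to branch length — i.e. conditioned on
the observed number of segregating sites. Default 10 000 replicates,
seed 20120511 (configurable); this simulator is written here because
off-the-shelf coalescent simulators condition on mutation rate, not S.

## MK tables and single-locus tests

A site is a fixed difference iff the ingroup and outgroup allele sets
are disjoint; sites segregating in either species contribute to that
species' polymorphism counts (a site both polymorphic and divergent
counts as polymorphism only). Changes are classified in the codon
context of the species' majority codon, change-by-change; fixed
differences in multi-hit codons are pathway-averaged between the two
majority codons, which can yield fractional event counts (tables are
rounded to integers when a 2×2 test table is formed).

The default MK test pools both species' polymorphism into the 2×2 table
— the convention under which the published G values of the source
dataset reproduce exactly. The Yates continuity correction shifts each
observed count 0.5 toward its expectation, clamped so it never crosses
it; G = 2 Σ o′ ln(o′/e) is referred to χ²₁. When all margins are
positive but the minimum expected count falls below 2, Fisher's exact
test (two-sided by point-probability summation) is used instead; a zero
margin makes the locus not testable. The threshold of 2 is a policy
choice (exposed as `min_expected`): the original analysis's G-vs-Fisher
row assignment is only partially recoverable, and 2 is the smallest
integer threshold consistent with the rows that are. Multiplicity is
handled with Benjamini–Hochberg FDR q-values over the testable loci.

## Multilocus model

Counts (P_s, P_n, D_s, D_n) per locus are independent Poisson with

    E[Ps_i] = L_s,i Θ_i,   E[Pn_i] = f_i L_n,i Θ_i,
    E[Ds_i] = L_s,i λ,     E[Dn_i] = f_i L_n,i λ/(1 − α_g(i)),

Θ_i = θ_in a(n_in,i) + θ_out a(n_out,i). Free parameters: θ_in, θ_out,
λ (> 0, shared across loci), f_i per locus (constraint, bounded to
(10⁻⁶, 100)), and α (< 1, bounded to (−10, 0.999)) with structure
M0/M1/M2/M3 (none/shared/per-locus/per-class), giving
k = 3 + L + {0, 1, L, 2} parameters and 4L observations. Given the
shared rates, the ML f_i has the closed form
(P_n,i + D_n,i)/(L_n,i(Θ_i + λ/(1 − α_i))), and for M2 the per-locus α
additionally solves E[Pn] = Pn, E[Dn] = Dn in closed form; both are
profiled out, leaving a 3–5-dimensional bounded L-BFGS-B problem
(rates on log scale), run from 5 seeded starts (moment-based plus
jittered; resampling refits warm-start at the full-data MLE with a
single start). Models are compared by LRT against M0, AICc
(−2lnL + 2k + 2k(k+1)/(n−k−1); undefined when n ≤ k+1, e.g. M2 on a
single locus) and Akaike weights.

Two conventions are exposed because the published analysis this package
reproduces does not document them and they are not recoverable from
first principles:

- `polymorphism` — which sample's polymorphism feeds the P
  observations. Default `"ingroup"`: the outgroup samples here are 1–4
  individuals, and the published class estimates reproduce only under
  ingroup-only counts. `"pooled"` adds the outgroup's counts (then
  θ_out is identified by them; with ingroup-only counts θ_out is driven
  to its lower bound and Θ is effectively the ingroup term).
- `sample_size_weights` — whether the Watterson factors a(n) enter Θ_i.
  Default True (the statistically natural form; when sample sizes are
  constant across loci, as in all synthetic data here, it is an exact
  reparameterization of equal weights). The bundled-dataset
  reproduction sets it False, matching multilocus MK software whose
  input carries no sample sizes; under equal weights the bundled data
  reproduce the published model-comparison table and class α values.

Class-level uncertainty: each class's loci are resampled with
replacement (the other class intact), M3 refitted, and 2.5/97.5%
quantiles of α̂ taken (10 000 replicates by default). The two-class
contrast is tested by permuting class labels (sizes preserved),
refitting, and comparing |Δα̂|, with p = (1 + #{≥ observed})/(reps + 1)
so p > 0. Per-locus summaries report the closed-form
α̂_i = 1 − D_s P_n/(D_n P_s) (missing when P_s = 0 or D_n = 0) and
a_i = α̂_i D_n/L_n, the adaptive nonsynonymous substitutions per
nonsynonymous site, which is robust to between-locus differences in
constraint.

When only counts and sequence lengths are available, site exposures are
approximated as L_n = 0.75 bp, L_s = 0.25 bp (configurable). Scale
errors in this split are absorbed by θ, λ and f and leave α unchanged;
per-locus differences from the true exposure ratio are not, which is the
main reason reproduced log-likelihoods differ from the original
software's by an additive amount while α, LRT and Akaike-weight
structure reproduce.

## Synthetic data

`simulate_counts` is the generative twin of the multilocus likelihood:
it draws per-locus counts from the exact Poisson means, with per-locus
constraint f_i ~ logNormal(−2, 1) clipped to (10⁻³, 1] (median ≈ 0.14,
matching the observed K_a/K_s scale) and defaults mirroring the bundled
study design: 47 loci split 21/26 between classes, θ_in = 0.03 (the
observed mean synonymous diversity), θ_out = 0.02, λ = 0.13 (the
observed mean synonymous divergence), lengths 300–1500 bp, 18 ingroup
and 5 outgroup haplotypes, class α = (−0.27, +0.33). `simulate_alignment`
plants exact numbers of synonymous/nonsynonymous polymorphisms (at
chosen carrier counts) and fixed differences at distinct codons of a
stop-free template, each verified against the genetic code at planting
time, so the sequence pipeline's recovered MK table equals the planted
counts by construction.

What the generator does **not** emulate: linkage and recombination
(counts are independent Poisson, alignments have no genealogical
correlation), multi-hit codons (planted events occupy distinct codons;
multi-hit classification is exercised by hand-built fixtures),
selection acting on the frequency spectrum, migration/structure, and
sequencing/phasing error. Passing recovery and coverage tests therefore
validate the estimator under its own model assumptions, not robustness
to their violation in real data.

## Numerical and design notes

- Optimizer: L-BFGS-B, ftol 10⁻¹², maxiter 500; the M2 per-locus α
  profile evaluates the interior stationary point and both bounds and
  keeps the best, so boundary cases (P_n = 0 or D_n = 0) are handled
  without special-casing.
- Problem sizes in the test suite are chosen for a single-CPU run:
  estimator recovery uses 100 simulations of 200 loci; bootstrap
  coverage 120 simulations × 100 replicates on 60 loci; permutation
  null calibration 100 simulations × 119 permutations on 40 loci;
  coalescent checks use 2 000 genealogies.
- Reports are written with fixed precision (4 dp for rates/π/K, 3 dp
  for G and D) and a config hash (excluding the output directory), so a
  rerun with the same configuration and seed is byte-identical.
- Known limitations: the likelihood ignores linkage between sites of a
  locus and between polymorphism and divergence; α of a class is not
  invariant to the exposure approximation at per-locus level; the
  coalescent null assumes panmixia and no recombination; fractional MK
  counts from multi-hit codons are rounded when 2×2 tables are formed.
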