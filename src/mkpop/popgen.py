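"""Per-locus diversity, divergence and frequency-spectrum statistics.

Synonymous and nonsynonymous site exposures and difference counts follow
Nei & Gojobori (1986); between-species divergence is Jukes-Cantor
corrected; Tajima's D is computed at synonymous sites and its
significance assessed against a standard neutral coalescent conditioned
on the observed number of segregating sites.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .align_io import HaplotypeAlignment
from .codon import codon_sites, is_synonymous_change, pathway_differences

DEFAULT_SEED = 20120511


@dataclass(frozen=True)
class SiteClassCounts:
    """Fractional synonymous (L_s) and nonsynonymous (L_n) site counts."""

    L_s: float
    L_n: float

    def __post_init__(self):
        if self.L_s < 0 or self.L_n < 0:
            raise ValueError("site counts must be non-negative")


@dataclass(frozen=True)
class TajimaResult:
    D: float  # NaN when undefined (S == 0)
    p: float  # one-tailed coalescent probability; NaN if not simulated
    n: int
    S: int


@dataclass(frozen=True)
class DiversitySummary:
    """Table-1-style per-locus summary."""

    locus_id: str
    pi_s: float
    pi_a: float
    K_s: float
    K_a: float
    theta_w_s: float
    S_s: int
    n_haplotypes_in: int
    n_haplotypes_out: int

    @property
    def ka_ks(self) -> float:
        return self.K_a / self.K_s if self.K_s > 0 else float("nan")


def count_sites(aln: HaplotypeAlignment) -> SiteClassCounts:
    """Nei-Gojobori syn/nonsyn site exposures, averaged over ingroup
    haplotypes; codon columns with gaps, N or stops are excluded."""
    cols = aln.codon_columns()
    if not cols:
        raise ValueError(f"{aln.locus_id}: no complete codon columns")
    n = len(aln.ingroup_haplotypes)
    ls = ln = 0.0
    for ins, _ in cols:
        for codon in ins:
            s, a = codon_sites(codon)
            ls += s / n
            ln += a / n
    return SiteClassCounts(L_s=ls, L_n=ln)


def _pair_differences(codons1: list[str], codons2: list[str]) -> tuple[float, float]:
    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        s, a = pathway_differences(c1, c2)
        sd += s
        nd += a
    return sd, nd


def pairwise_diversity(
    aln: HaplotypeAlignment, per_site: bool = True
) -> tuple[float, float]:
    """Average pairwise (pi_s, pi_a) over all ingroup haplotype pairs.

    With ``per_site=False`` returns total average pairwise synonymous and
    nonsynonymous differences (the inputs Tajima's D needs).
    """
    if len(aln.ingroup_haplotypes) < 2:
        raise ValueError(f"{aln.locus_id}: need >=2 ingroup haplotypes")
    cols = aln.codon_columns()
    if not cols:
        raise ValueError(f"{aln.locus_id}: no complete codon columns")
    by_hap = list(zip(*(ins for ins, _ in cols)))  # codons per haplotype
    pairs = list(combinations(range(len(by_hap)), 2))
    sd_tot = nd_tot = 0.0
    for i, j in pairs:
        sd, nd = _pair_differences(list(by_hap[i]), list(by_hap[j]))
        sd_tot += sd
        nd_tot += nd
    mean_sd = sd_tot / len(pairs)
    mean_nd = nd_tot / len(pairs)
    if not per_site:
        return mean_sd, mean_nd
    sites = count_sites(aln)
    pi_s = mean_sd / sites.L_s if sites.L_s > 0 else float("nan")
    pi_a = mean_nd / sites.L_n if sites.L_n > 0 else float("nan")
    return pi_s, pi_a


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a raw proportion."""
    if p >= 0.75:
        warnings.warn(f"JC correction undefined for proportion {p:.4f} >= 0.75")
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def divergence(
    aln: HaplotypeAlignment, jc_correct: bool = True
) -> tuple[float, float]:
    """Mean between-species (K_s, K_a) over all ingroup x outgroup pairs,
    Jukes-Cantor corrected by default."""
    if not aln.outgroup_haplotypes:
        raise ValueError(f"{aln.locus_id}: no outgroup haplotypes")
    cols = aln.codon_columns()
    if not cols:
        raise ValueError(f"{aln.locus_id}: no complete codon columns")
    in_by_hap = list(zip(*(ins for ins, _ in cols)))
    out_by_hap = list(zip(*(outs for _, outs in cols)))
    sites = count_sites(aln)
    sd_tot = nd_tot = 0.0
    npairs = 0
    for hi, ho in product(in_by_hap, out_by_hap):
        sd, nd = _pair_differences(list(hi), list(ho))
        sd_tot += sd
        nd_tot += nd
        npairs += 1
    p_s = sd_tot / npairs / sites.L_s if sites.L_s > 0 else float("nan")
    p_a = nd_tot / npairs / sites.L_n if sites.L_n > 0 else float("nan")
    if not jc_correct:
        return p_s, p_a
    ks = jukes_cantor(p_s) if not math.isnan(p_s) else p_s
    ka = jukes_cantor(p_a) if not math.isnan(p_a) else p_a
    return ks, ka


def harmonic(n: int) -> float:
    """a(n) = sum_{i=1}^{n-1} 1/i (0 for n < 2)."""
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's theta per site: S / (L * a(n))."""
    if n < 2:
        raise ValueError(f"need n >= 2 haplotypes, got {n}")
    if L <= 0:
        raise ValueError(f"need positive site count, got {L}")
    return S / (L * harmonic(n))


def synonymous_segregating_sites(aln: HaplotypeAlignment) -> int:
    """Number of ingroup segregating sites whose variants are all
    synonymous against the ingroup major-allele codon background."""
    S = 0
    for ins, _ in aln.codon_columns():
        counts = Counter(ins)
        major = min(c for c, k in counts.items() if k == max(counts.values()))
        for pos in range(3):
            states = {c[pos] for c in ins}
            if len(states) < 2:
                continue
            if all(
                is_synonymous_change(major, pos, b)
                for b in states
                if b != major[pos]
            ):
                S += 1
    return S


def tajima_d_from_counts(n: int, S: int, pi_total: float) -> float:
    """Tajima (1989) D from sample size, segregating sites and the total
    (not per-site) average pairwise difference count."""
    if n < 3:
        raise ValueError(f"Tajima's D needs n >= 3, got {n}")
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        # at n = 3 the variance coefficients vanish identically and
        # pi equals S/a1 for any configuration, so D is defined as 0
        return 0.0 if abs(pi_total - S / a1) < 1e-9 else float("nan")
    return (pi_total - S / a1) / math.sqrt(var)


def tajima_d(aln: HaplotypeAlignment) -> TajimaResult:
    """Tajima's D at synonymous sites for the ingroup sample (p is left
    NaN; use :func:`tajima_p_coalescent` for significance)."""
    n = len(aln.ingroup_haplotypes)
    if n < 3:
        raise ValueError(f"{aln.locus_id}: Tajima's D skipped, n={n} < 3")
    S = synonymous_segregating_sites(aln)
    pi_total, _ = pairwise_diversity(aln, per_site=False)
    D = tajima_d_from_counts(n, S, pi_total) if S > 0 else float("nan")
    return TajimaResult(D=D, p=float("nan"), n=n, S=S)


def _simulate_neutral_d(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Tajima's D under the standard neutral coalescent for samples of
    ``n``, conditioning on ``S`` segregating sites.

    Kingman genealogies are simulated (exponential coalescence times,
    uniformly chosen pairs); the S mutations fall on branches with
    probability proportional to branch length, each on its own site
    (infinite-sites).  D is computed from the resulting frequency
    spectrum.
    """
    ds = np.empty(reps)
    pair_norm = n * (n - 1) / 2.0
    for r in range(reps):
        sizes = [1] * n  # leaves subtended by each active lineage
        branch_sizes: list[int] = []
        branch_lens: list[float] = []
        k = n
        while k > 1:
            t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
            for sz in sizes:
                branch_sizes.append(sz)
                branch_lens.append(t)
            i, j = rng.choice(k, size=2, replace=False)
            merged = sizes[i] + sizes[j]
            sizes = [s for idx, s in enumerate(sizes) if idx not in (i, j)]
            sizes.append(merged)  # accrues length in later intervals only
            k -= 1
        lens = np.array(branch_lens)
        szs = np.array(branch_sizes)
        picks = rng.choice(len(lens), size=S, p=lens / lens.sum())
        counts = szs[picks]
        pi = float(np.sum(counts * (n - counts)) / pair_norm)
        ds[r] = tajima_d_from_counts(n, S, pi)
    return ds


def tajima_p_coalescent(
    n: int,
    S: int,
    D_obs: float,
    reps: int = 10000,
    seed: int = DEFAULT_SEED,
) -> float:
    """One-tailed coalescent probability of a Tajima's D as extreme as
    ``D_obs`` in the direction of its sign, conditioning on S."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if S < 1:
        raise ValueError(f"need S >= 1, got {S}")
    if reps < 100:
        raise ValueError(f"need reps >= 100, got {reps}")
    rng = np.random.default_rng(seed)
    sims = _simulate_neutral_d(n, S, reps, rng)
    if D_obs > 0:
        return float(np.mean(sims >= D_obs))
    return float(np.mean(sims <= D_obs))


def locus_summary(
    aln: HaplotypeAlignment,
    coalescent_reps: int = 10000,
    seed: int = DEFAULT_SEED,
) -> tuple[DiversitySummary, TajimaResult]:
    """All Table-1-style statistics for one locus."""
    from .align_io import count_haplotypes

    pi_s, pi_a = pairwise_diversity(aln)
    ks, ka = divergence(aln)
    n = len(aln.ingroup_haplotypes)
    sites = count_sites(aln)
    S_s = synonymous_segregating_sites(aln)
    theta = watterson_theta(S_s, n, sites.L_s) if n >= 2 and sites.L_s > 0 else float("nan")
    h_in, h_out = count_haplotypes(aln)
    summary = DiversitySummary(
        locus_id=aln.locus_id,
        pi_s=pi_s,
        pi_a=pi_a,
        K_s=ks,
        K_a=ka,
        theta_w_s=theta,
        S_s=S_s,
        n_haplotypes_in=h_in,
        n_haplotypes_out=h_out,
    )
    if n >= 3:
        taj = tajima_d(aln)
        if taj.S > 0 and math.isfinite(taj.D):
            p = tajima_p_coalescent(n, taj.S, taj.D, reps=coalescent_reps, seed=seed)
            taj = TajimaResult(D=taj.D, p=p, n=taj.n, S=taj.S)
    else:
        taj = TajimaResult(D=float("nan"), p=float("nan"), n=n, S=S_s)
    return summary, taj
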