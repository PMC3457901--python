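"""Synthetic data with the statistical structure the analysis assumes.

Two entry points share one configuration: ``simulate_counts`` draws
per-locus (Ps, Pn, Ds, Dn) from the exact Poisson means of the
multilocus likelihood (its generative twin), and ``simulate_alignment``
plants verified synonymous/nonsynonymous polymorphisms and fixed
differences into codon sequences so the sequence pipeline can be tested
end to end.

Defaults mirror the Daphnia study design: ~47 loci in two classes,
ingroup synonymous diversity ~0.03/site, shared synonymous divergence
~0.13/site, a handful of outgroup chromosomes, and class alphas of
-0.27 (non-immune) and 0.33 (immune).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align_io import HaplotypeAlignment
from .codon import BASES, amino_acid, is_stop, is_valid_codon
from .mk_counts import MKTable
from .mk_multilocus import CLASSES, LocusRecord
from .popgen import harmonic


@dataclass(frozen=True)
class SimConfig:
    n_loci: int = 47
    class_fractions: tuple[float, float] = (21 / 47, 26 / 47)  # (nonimmune, immune)
    theta_in: float = 0.03
    theta_out: float = 0.02
    lam: float = 0.13
    f_lognorm_mu: float = -2.0  # median constraint ~0.14
    f_lognorm_sigma: float = 1.0
    alpha_by_class: tuple[float, float] = (-0.27, 0.33)  # (nonimmune, immune)
    length_range: tuple[int, int] = (300, 1500)  # bp
    sample_sizes: tuple[int, int] = (18, 5)  # phased haplotypes (in, out)
    ln_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("need n_loci >= 1")
        if min(self.theta_in, self.theta_out, self.lam) <= 0:
            raise ValueError("rates must be positive")
        if max(self.alpha_by_class) >= 1:
            raise ValueError("alpha must be < 1")


def simulate_counts(config: SimConfig) -> list[LocusRecord]:
    """Draw independent loci from the multilocus model's exact means.

    Each record carries its true constraint f_i (as metadata via the
    returned frame from :func:`simulate_counts_frame`) and class label,
    so estimator-recovery tests can compare against truth.
    """
    records, _ = simulate_counts_with_truth(config)
    return records


def simulate_counts_with_truth(
    config: SimConfig,
) -> tuple[list[LocusRecord], dict]:
    """As :func:`simulate_counts`, also returning the generating truth
    (per-locus f_i, alpha_i and the shared rates)."""
    rng = np.random.default_rng(config.seed)
    n_in, n_out = config.sample_sizes
    h_in, h_out = harmonic(n_in), harmonic(n_out)
    n_non = int(round(config.n_loci * config.class_fractions[0]))
    classes = np.array([0] * n_non + [1] * (config.n_loci - n_non))
    lengths = rng.integers(
        config.length_range[0] // 3, config.length_range[1] // 3 + 1,
        size=config.n_loci,
    ) * 3
    f = np.clip(
        rng.lognormal(config.f_lognorm_mu, config.f_lognorm_sigma, config.n_loci),
        1e-3, 1.0,
    )
    alpha = np.asarray(config.alpha_by_class)[classes]
    Ls = (1.0 - config.ln_fraction) * lengths
    Ln = config.ln_fraction * lengths
    theta_i = config.theta_in * h_in
    theta_o = config.theta_out * h_out
    records = []
    for i in range(config.n_loci):
        ps_in = rng.poisson(Ls[i] * theta_i)
        ps_out = rng.poisson(Ls[i] * theta_o)
        pn_in = rng.poisson(f[i] * Ln[i] * theta_i)
        pn_out = rng.poisson(f[i] * Ln[i] * theta_o)
        ds = rng.poisson(Ls[i] * config.lam)
        dn = rng.poisson(f[i] * Ln[i] * config.lam / (1.0 - alpha[i]))
        records.append(
            LocusRecord(
                locus_id=f"locus_{i:03d}",
                gene_class=CLASSES[classes[i]],
                mk=MKTable(
                    pn_in=float(pn_in), ps_in=float(ps_in),
                    pn_out=float(pn_out), ps_out=float(ps_out),
                    dn=float(dn), ds=float(ds),
                ),
                L_s=float(Ls[i]), L_n=float(Ln[i]),
                n_in=n_in, n_out=n_out,
            )
        )
    truth = dict(
        f=f, alpha=alpha, classes=classes,
        theta_in=config.theta_in, theta_out=config.theta_out, lam=config.lam,
    )
    return records, truth


# ---------------------------------------------------------------------------
# sequence-level simulation


class GenerationError(RuntimeError):
    """Not enough eligible codons to plant the requested events."""


@dataclass(frozen=True)
class PlantedCounts:
    """Events to plant into one simulated locus alignment."""

    Ps: int = 0
    Pn: int = 0
    Ds: int = 0
    Dn: int = 0
    # ingroup carrier counts for polymorphic variants; defaults to a
    # single mid-frequency carrier count of n_in // 2
    carriers: tuple[int, ...] = field(default=())


def _random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(list(BASES), size=3))
        if not is_stop(c):
            codons.append(c)
    return codons


def _mutations(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """All single-base changes of the requested class (never to a stop)."""
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mut):
                continue
            if (amino_acid(mut) == amino_acid(codon)) == synonymous:
                out.append((pos, b))
    return out


def simulate_alignment(
    config: SimConfig,
    planted: PlantedCounts,
    locus_id: str = "sim_locus",
    template: str | None = None,
    rng: np.random.Generator | None = None,
) -> HaplotypeAlignment:
    """Plant exact (Ps, Pn, Ds, Dn) events into a codon alignment.

    Every event lands at its own codon and is verified against the
    genetic code at planting time, so ``build_mk_table`` on the result
    recovers the planted counts exactly.  Polymorphic variants are
    carried by ``carriers`` ingroup haplotypes (default: half the
    sample); fixed differences are carried by all outgroup haplotypes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_in, n_out = config.sample_sizes
    n_events = planted.Ps + planted.Pn + planted.Ds + planted.Dn
    if template is not None:
        codons = [template[i : i + 3] for i in range(0, len(template), 3)]
        if not all(is_valid_codon(c) and not is_stop(c) for c in codons):
            raise GenerationError("template must be stop-free sense codons")
    else:
        codons = _random_sense_codons(
            max(n_events * 3, config.length_range[0] // 3), rng
        )
    if n_events > len(codons):
        raise GenerationError(
            f"{n_events} events will not fit in {len(codons)} codons"
        )
    n_poly = planted.Ps + planted.Pn
    carriers = planted.carriers or tuple([max(n_in // 2, 1)] * n_poly)
    if len(carriers) != n_poly:
        raise GenerationError("need one carrier count per polymorphic event")
    if any(not 1 <= c < n_in for c in carriers):
        raise GenerationError("carrier counts must be in [1, n_in)")

    slots = rng.permutation(len(codons))
    ingroup = [list(codons) for _ in range(n_in)]
    out_template = list(codons)
    si = 0

    def plant_poly(synonymous: bool, carrier: int):
        nonlocal si
        while True:
            if si >= len(slots):
                raise GenerationError("ran out of eligible codons")
            slot = slots[si]
            si += 1
            options = _mutations(codons[slot], synonymous)
            if options:
                break
        pos, b = options[rng.integers(len(options))]
        mutant = codons[slot][:pos] + b + codons[slot][pos + 1 :]
        for hap in rng.choice(n_in, size=carrier, replace=False):
            ingroup[hap][slot] = mutant

    def plant_fixed(synonymous: bool):
        nonlocal si
        while True:
            if si >= len(slots):
                raise GenerationError("ran out of eligible codons")
            slot = slots[si]
            si += 1
            options = _mutations(codons[slot], synonymous)
            if options:
                break
        pos, b = options[rng.integers(len(options))]
        out_template[slot] = codons[slot][:pos] + b + codons[slot][pos + 1 :]

    ci = 0
    for _ in range(planted.Ps):
        plant_poly(True, carriers[ci])
        ci += 1
    for _ in range(planted.Pn):
        plant_poly(False, carriers[ci])
        ci += 1
    for _ in range(planted.Ds):
        plant_fixed(True)
    for _ in range(planted.Dn):
        plant_fixed(False)

    return HaplotypeAlignment(
        locus_id=locus_id,
        ingroup_haplotypes=tuple("".join(h) for h in ingroup),
        outgroup_haplotypes=tuple("".join(out_template) for _ in range(n_out)),
        frame_offset=0,
        sample_labels=tuple(
            ["D_pulex"] * n_in + ["D_parvula"] * n_out
        ),
    )


def write_fasta(aln: HaplotypeAlignment, path, ingroup_species="D_pulex",
                outgroup_species="D_parvula") -> None:
    """Write an alignment in the FASTA convention ``read_locus_alignment``
    expects (species= tags in the description)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(aln.ingroup_haplotypes):
            fh.write(f">{aln.locus_id}_in{i} species={ingroup_species}\n{seq}\n")
        for i, seq in enumerate(aln.outgroup_haplotypes):
            fh.write(f">{aln.locus_id}_out{i} species={outgroup_species}\n{seq}\n")
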