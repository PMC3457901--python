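"""Building the per-locus McDonald-Kreitman 2x2 table.

A nucleotide site is a fixed difference iff the ingroup and outgroup
allele sets are disjoint; a site segregating within either species
contributes to that species' polymorphism counts.  Each change is
classified synonymous/nonsynonymous in the codon context of the species'
major-allele background; codons carrying several changes are resolved by
equal-weight pathway enumeration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .align_io import HaplotypeAlignment
from .codon import is_synonymous_change, pathway_differences


@dataclass(frozen=True)
class MKTable:
    """Polymorphism and divergence counts for one locus.

    Counts are floats because pathway averaging of multi-hit codons can
    split one event across classes; they are integral whenever every
    variant codon carries a single change.
    """

    pn_in: float = 0.0
    ps_in: float = 0.0
    pn_out: float = 0.0
    ps_out: float = 0.0
    dn: float = 0.0
    ds: float = 0.0

    @property
    def Pn(self) -> float:
        return self.pn_in + self.pn_out

    @property
    def Ps(self) -> float:
        return self.ps_in + self.ps_out

    @property
    def Dn(self) -> float:
        return self.dn

    @property
    def Ds(self) -> float:
        return self.ds


def _major(codons: list[str]) -> str:
    counts = Counter(codons)
    top = max(counts.values())
    return min(c for c, k in counts.items() if k == top)


def _polymorphism_events(codons: list[str]) -> tuple[float, float]:
    """(syn, nonsyn) polymorphic changes in one species' codon column,
    decomposed change-by-change against the majority codon."""
    major = _major(codons)
    syn = nonsyn = 0.0
    for pos in range(3):
        for b in {c[pos] for c in codons} - {major[pos]}:
            if is_synonymous_change(major, pos, b):
                syn += 1.0
            else:
                nonsyn += 1.0
    return syn, nonsyn


def build_mk_table(aln: HaplotypeAlignment) -> MKTable:
    """Classify every variable site of a validated (and, for the standard
    workflow, frequency-filtered) alignment into the MK table."""
    if len(aln.ingroup_haplotypes) < 2:
        raise ValueError(f"{aln.locus_id}: need >=2 ingroup haplotypes")
    if not aln.outgroup_haplotypes:
        raise ValueError(f"{aln.locus_id}: need >=1 outgroup haplotype")
    pn_in = ps_in = pn_out = ps_out = dn = ds = 0.0
    for ins, outs in aln.codon_columns():
        s, a = _polymorphism_events(ins)
        ps_in += s
        pn_in += a
        if len(outs) > 1:
            s, a = _polymorphism_events(outs)
            ps_out += s
            pn_out += a
        in_major = _major(ins)
        out_major = _major(outs)
        fixed_pos = [
            p
            for p in range(3)
            if not ({c[p] for c in ins} & {c[p] for c in outs})
        ]
        if fixed_pos:
            # pathway-average between the two majority codons restricted
            # to the truly fixed positions, on the ingroup background
            target = "".join(
                out_major[p] if p in fixed_pos else in_major[p] for p in range(3)
            )
            s, a = pathway_differences(in_major, target)
            ds += s
            dn += a
    return MKTable(
        pn_in=pn_in, ps_in=ps_in, pn_out=pn_out, ps_out=ps_out, dn=dn, ds=ds
    )


def pool_polymorphism(table: MKTable, mode: str = "pooled") -> np.ndarray:
    """2x2 integer contingency table: rows (polymorphism, divergence),
    columns (nonsynonymous, synonymous).

    ``pooled`` sums ingroup and outgroup polymorphism (the default used
    for MK testing); ``ingroup_only`` uses the ingroup's counts alone.
    """
    if mode == "pooled":
        pn, ps = table.Pn, table.Ps
    elif mode == "ingroup_only":
        pn, ps = table.pn_in, table.ps_in
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return np.rint([[pn, ps], [table.Dn, table.Ds]]).astype(int)
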