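"""Codon-level primitives for synonymous/nonsynonymous counting.

Implements the Nei & Gojobori (1986) conventions used throughout the
package: fractional synonymous/nonsynonymous site counts per codon, and
equal-weight averaging over mutational pathways when two codons differ at
more than one position.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

_FORWARD = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def amino_acid(codon: str) -> str:
    """One-letter amino acid for ``codon``; '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return _FORWARD[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each of the nine single-base changes contributes 1/3 of a site to the
    synonymous class if it preserves the amino acid, else to the
    nonsynonymous class.  Changes that create a stop codon count as
    nonsynonymous, so the two classes always sum to exactly 3 sites.
    """
    if not is_valid_codon(codon) or is_stop(codon):
        raise ValueError(f"not a countable sense codon: {codon!r}")
    aa = amino_acid(codon)
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if amino_acid(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Codons differing at k positions are connected by k! mutational
    pathways of single-base steps; each step is classified by whether it
    preserves the amino acid.  Pathways passing through a stop codon are
    excluded (unless every pathway does, in which case all are kept so the
    total difference count is preserved).  Pathways are weighted equally.
    """
    for c in (codon1, codon2):
        if not is_valid_codon(c) or is_stop(c):
            raise ValueError(f"not a countable sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, clean)
    for order in permutations(diff_pos):
        cur = codon1
        syn = nonsyn = 0.0
        clean = True
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                clean = False
                # classify the step anyway (stop = nonsynonymous)
                nonsyn += 1.0
            elif amino_acid(nxt) == amino_acid(cur) and not is_stop(cur):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        paths.append((syn, nonsyn, clean))
    usable = [p for p in paths if p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def is_synonymous_change(codon: str, pos: int, new_base: str) -> bool:
    """Whether substituting ``new_base`` at ``pos`` of ``codon`` preserves
    the amino acid (a change to a stop codon is nonsynonymous)."""
    mutant = codon[:pos] + new_base + codon[pos + 1 :]
    if is_stop(mutant) or is_stop(codon):
        return False
    return amino_acid(mutant) == amino_acid(codon)
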