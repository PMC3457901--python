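"""Reading, validating and filtering per-locus codon alignments.

A locus is represented by a :class:`HaplotypeAlignment`: phased CDS
haplotypes of an ingroup species plus one or more haplotypes of an
outgroup species, aligned in a common reading frame.  Phasing is assumed
to have happened upstream; this module only stores and validates its
product.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

ALPHABET = frozenset("ACGTN-")

MANIFEST_COLUMNS = [
    "locus_id",
    "class",
    "outgroup_species",
    "include_multilocus",
    "frame_offset",
]


class AlignmentFormatError(ValueError):
    """Malformed alignment (unequal lengths, bad alphabet, bad frame)."""


class ManifestError(ValueError):
    """Manifest missing columns or inconsistent with a FASTA file."""


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Phased, codon-aligned haplotypes of one locus for two species."""

    locus_id: str
    ingroup_haplotypes: tuple[str, ...]
    outgroup_haplotypes: tuple[str, ...]
    frame_offset: int = 0
    sample_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        seqs = self.ingroup_haplotypes + self.outgroup_haplotypes
        if not self.ingroup_haplotypes:
            raise AlignmentFormatError(f"{self.locus_id}: no ingroup haplotypes")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise AlignmentFormatError(
                f"{self.locus_id}: frame_offset must be 0-2, got {self.frame_offset}"
            )
        if (lengths.pop() - self.frame_offset) // 3 < 1:
            raise AlignmentFormatError(f"{self.locus_id}: fewer than one usable codon")
        bad = set("".join(seqs)) - ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"{self.locus_id}: disallowed characters {sorted(bad)}"
            )

    @property
    def n_codons(self) -> int:
        return (len(self.ingroup_haplotypes[0]) - self.frame_offset) // 3

    def codon_columns(self) -> list[tuple[list[str], list[str]]]:
        """Codon columns passing complete deletion.

        A column is kept only if every haplotype (both species) shows a
        gap-free, N-free sense codon there; columns where any haplotype
        carries a stop are dropped too, so site exposures are common to
        all downstream statistics.
        """
        from .codon import is_stop, is_valid_codon

        cols = []
        for c in range(self.n_codons):
            lo = self.frame_offset + 3 * c
            ins = [s[lo : lo + 3] for s in self.ingroup_haplotypes]
            outs = [s[lo : lo + 3] for s in self.outgroup_haplotypes]
            if all(is_valid_codon(x) and not is_stop(x) for x in ins + outs):
                cols.append((ins, outs))
        return cols


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a locus manifest TSV; required columns are validated."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    bad = set(df["class"]) - {"immune", "nonimmune"}
    if bad:
        raise ManifestError(f"unknown class labels: {sorted(bad)}")
    return df


def read_locus_alignment(
    fasta_path: str | Path,
    manifest_entry,
    ingroup_species: str = "D_pulex",
) -> HaplotypeAlignment:
    """Read one locus FASTA and partition records by species.

    Each record's description must carry a ``species=<tag>`` token; tags
    equal to the manifest entry's ``outgroup_species`` go to the outgroup
    partition, tags equal to ``ingroup_species`` to the ingroup.  Any
    other tag is a manifest/header mismatch.
    """
    entry = dict(manifest_entry)
    outgroup_species = str(entry["outgroup_species"])
    frame_offset = int(entry.get("frame_offset", 0))
    locus_id = str(entry["locus_id"])

    ingroup, outgroup, labels = [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t
        )
        species = tokens.get("species")
        if species is None:
            raise ManifestError(
                f"{locus_id}: record {rec.id!r} lacks a species= tag"
            )
        seq = str(rec.seq).upper()
        if species == outgroup_species:
            outgroup.append(seq)
        elif species == ingroup_species:
            ingroup.append(seq)
        else:
            raise ManifestError(
                f"{locus_id}: record {rec.id!r} has unknown species {species!r}"
            )
        labels.append(species)
    if not ingroup or not outgroup:
        raise ManifestError(
            f"{locus_id}: empty species partition "
            f"(ingroup={len(ingroup)}, outgroup={len(outgroup)})"
        )
    return HaplotypeAlignment(
        locus_id=locus_id,
        ingroup_haplotypes=tuple(ingroup),
        outgroup_haplotypes=tuple(outgroup),
        frame_offset=frame_offset,
        sample_labels=tuple(labels),
    )


def filter_low_frequency_variants(
    aln: HaplotypeAlignment, threshold: float = 0.10
) -> HaplotypeAlignment:
    """Mask rare segregating variants in the ingroup sample.

    At every alignment column, any A/C/G/T state whose relative frequency
    among ingroup haplotypes is strictly below ``threshold`` is replaced
    by the ingroup major state (ties broken alphabetically).  This
    removes putatively mildly deleterious low-frequency alleles before
    polymorphism-based analyses without altering sample sizes or site
    exposures.  Gap/N characters and the outgroup are untouched.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if len(aln.ingroup_haplotypes) < 2:
        raise ValueError(f"{aln.locus_id}: need >=2 ingroup haplotypes to filter")

    seqs = [list(s) for s in aln.ingroup_haplotypes]
    n = len(seqs)
    for j in range(len(seqs[0])):
        counts = Counter(s[j] for s in seqs if s[j] in "ACGT")
        total = sum(counts.values())
        if total == 0 or len(counts) < 2:
            continue
        top = max(counts.values())
        major = min(b for b, c in counts.items() if c == top)
        rare = {b for b, c in counts.items() if c / total < threshold}
        rare.discard(major)
        if not rare:
            continue
        for s in seqs:
            if s[j] in rare:
                s[j] = major
    return replace(aln, ingroup_haplotypes=tuple("".join(s) for s in seqs))


def count_haplotypes(aln: HaplotypeAlignment) -> tuple[int, int]:
    """Number of distinct haplotype sequences per species partition."""
    n_out = len(set(aln.outgroup_haplotypes))
    if n_out == 0:
        warnings.warn(f"{aln.locus_id}: empty outgroup partition")
    return len(set(aln.ingroup_haplotypes)), n_out
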