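import numpy as np
import pytest

from mkpop import HaplotypeAlignment, datasets


@pytest.fixture(scope="session")
def locus_records():
    """Bundled 54-locus count dataset."""
    return datasets.load_locus_records()


@pytest.fixture(scope="session")
def multilocus_records():
    """The 47 loci retained for the multilocus model."""
    return datasets.load_locus_records(multilocus_only=True)


@pytest.fixture
def toy_alignment():
    """Five-codon alignment with one synonymous ingroup polymorphism and
    one synonymous + one nonsynonymous fixed difference."""
    return HaplotypeAlignment(
        locus_id="toy",
        ingroup_haplotypes=(
            "ATGAAAGGGTTTCCC",
            "ATGAAGGGGTTTCCC",  # AAA->AAG synonymous (Lys)
            "ATGAAAGGGTTTCCC",
        ),
        outgroup_haplotypes=(
            "ATGAAAGGCTATCCC",  # GGG->GGC fixed syn; TTT->TAT fixed nonsyn
        ),
    )


def random_alignment(seed: int, n_in: int = 6, n_out: int = 2, n_codons: int = 30):
    """Random mutation-sprinkled alignment for property tests."""
    rng = np.random.default_rng(seed)
    from mkpop.codon import BASES, is_stop

    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if not is_stop(c):
            codons.append(c)
    base = "".join(codons)

    def mutate(seq, n_mut):
        s = list(seq)
        for _ in range(n_mut):
            j = rng.integers(len(s))
            s[j] = "ACGT"[rng.integers(4)]
        return "".join(s)

    def no_stops(seq):
        return all(not is_stop(seq[i : i + 3]) for i in range(0, len(seq), 3))

    ingroup, outgroup = [], []
    while len(ingroup) < n_in:
        s = mutate(base, rng.integers(0, 5))
        if no_stops(s):
            ingroup.append(s)
    while len(outgroup) < n_out:
        s = mutate(base, rng.integers(3, 8))
        if no_stops(s):
            outgroup.append(s)
    return HaplotypeAlignment(
        locus_id=f"rand{seed}",
        ingroup_haplotypes=tuple(ingroup),
        outgroup_haplotypes=tuple(outgroup),
    )
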