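import numpy as np
import pytest

from hlaimpute import (
    Allele,
    AlleleSet,
    AmbiguousMultiLocusTyping,
    Haplotype,
    HaplotypeFrequencyTable,
)


def allele(locus: str, f1: int, f2: int | None = None) -> Allele:
    return Allele(locus, f"{f1:02d}", None if f2 is None else f"{f2:02d}")


def hap(*specs) -> Haplotype:
    """hap(("A",1,1),("B",7,2)) -> A*01:01~B*07:02"""
    return Haplotype(tuple(allele(*s) for s in specs))


def typing_from_sets(*per_locus) -> AmbiguousMultiLocusTyping:
    """per_locus: (locus, set1_alleles, set2_alleles)"""
    slots = []
    for locus, s1, s2 in per_locus:
        slots.append(
            (
                AlleleSet(locus, frozenset(s1), "explicit"),
                AlleleSet(locus, frozenset(s2), "explicit"),
            )
        )
    return AmbiguousMultiLocusTyping(tuple(slots))


def unambiguous_typing(genotype) -> AmbiguousMultiLocusTyping:
    slots = []
    for lg in genotype.genotypes:
        a, b = lg.alleles
        slots.append(
            (
                AlleleSet(lg.locus, frozenset({a}), "explicit"),
                AlleleSet(lg.locus, frozenset({b}), "explicit"),
            )
        )
    return AmbiguousMultiLocusTyping(tuple(slots))


def first_field_typing(genotype) -> AmbiguousMultiLocusTyping:
    """Mask a genotype to first-field groups against its own alleles only."""
    slots = []
    for lg in genotype.genotypes:
        a, b = lg.alleles
        slots.append(
            (
                AlleleSet(lg.locus, frozenset({a}), "first_field_mask"),
                AlleleSet(lg.locus, frozenset({b}), "first_field_mask"),
            )
        )
    return AmbiguousMultiLocusTyping(tuple(slots))


def random_instance(rng, n_loci=None, n_haps=None, ambiguous=True):
    """A random small frequency table plus a typing drawn from it.

    Used by brute-force-oracle tests: <=4 haplotypes over <=3 loci,
    typing slots optionally widened to 2-allele candidate sets.
    """
    loci = ["A", "B", "C"][: (n_loci or rng.integers(1, 4))]
    n_haps = min(int(n_haps or rng.integers(2, 5)), 3 ** len(loci))
    alleles = {l: [allele(l, 1, k + 1) for k in range(3)] for l in loci}
    haps = set()
    while len(haps) < n_haps:
        haps.add(tuple(alleles[l][rng.integers(3)] for l in loci))
    haps = [Haplotype(h) for h in sorted(haps, key=str)]
    freqs = rng.dirichlet(np.ones(n_haps))
    table = HaplotypeFrequencyTable(haps, freqs)

    i, j = rng.integers(n_haps), rng.integers(n_haps)
    h1, h2 = haps[i], haps[j]
    slots = []
    for l in loci:
        s = []
        for truth_allele in (h1.at(l), h2.at(l)):
            cand = {truth_allele}
            if ambiguous and rng.random() < 0.6:
                cand.add(alleles[l][rng.integers(3)])
            s.append(AlleleSet(l, frozenset(cand), "explicit"))
        slots.append(tuple(s))
    typing = AmbiguousMultiLocusTyping(tuple(slots))
    return table, typing, (h1, h2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
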