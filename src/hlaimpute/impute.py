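"""Allele-level multi-locus genotype imputation from ambiguous typings.

Given a haplotype frequency table and an ambiguous typing, every
consistent phased haplotype pair receives its Hardy-Weinberg prior
(2 f_i f_j for heterozygous pairs, f_i^2 for homozygous ones); pairs
collapsing to the same unphased genotype are summed, and the result is
renormalized over the candidate set.  The top candidate is the
imputation call; the typing resolution score (TRS) summarizes the
residual ambiguity of the whole distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from .em import Haplotype, HaplotypeFrequencyTable, unphase
from .model import (
    AmbiguousMultiLocusTyping,
    LocusGenotype,
    MultiLocusUnphasedGenotype,
)


@dataclass
class GenotypeDistribution:
    """Normalized probabilities over candidate unphased genotypes.

    ``unnormalized_mass`` keeps the total population genotype
    probability of the candidate set before renormalization.
    """

    donor_id: str
    candidates: dict[MultiLocusUnphasedGenotype, float]
    unnormalized_mass: float = 0.0

    @property
    def unexplainable(self) -> bool:
        return not self.candidates

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass
class ImputationResult:
    donor_id: str
    top: MultiLocusUnphasedGenotype | None
    top_probability: float
    trs: float
    n_candidates: int
    tie_broken: bool = False
    unexplainable: bool = False


def genotype_distribution(
    typing: AmbiguousMultiLocusTyping,
    table: HaplotypeFrequencyTable,
    donor_id: str = "",
) -> GenotypeDistribution:
    """Probability distribution over unphased genotypes given a typing.

    An empty distribution (no haplotype pair in the table explains the
    typing) is returned as an explicit unexplainable result rather than
    raised: unexplained donors are a reportable study outcome.
    """
    unions = {p[0].locus: p[0].candidates | p[1].candidates for p in typing.slots}
    loci = typing.loci
    cand: list[tuple[Haplotype, float]] = [
        (h, f)
        for h, f in table.items()
        if all(h.at(l) in unions[l] for l in loci)
    ]

    slot_pairs = typing.slots
    mass: dict[tuple, float] = {}
    haps: dict[tuple, tuple[Haplotype, Haplotype]] = {}
    n = len(cand)
    for i in range(n):
        h1, f1 = cand[i]
        a1 = h1.alleles
        for j in range(i, n):
            h2, f2 = cand[j]
            a2 = h2.alleles
            ok = True
            for (s1, s2), x, y in zip(slot_pairs, a1, a2):
                if not ((x in s1 and y in s2) or (x in s2 and y in s1)):
                    ok = False
                    break
            if not ok:
                continue
            prior = f1 * f2 if i == j else 2.0 * f1 * f2
            key = tuple((x, y) if x <= y else (y, x) for x, y in zip(a1, a2))
            mass[key] = mass.get(key, 0.0) + prior
            haps.setdefault(key, (h1, h2))

    total = sum(mass.values())
    if total <= 0.0:
        return GenotypeDistribution(donor_id, {}, 0.0)
    out = {
        MultiLocusUnphasedGenotype(
            tuple(LocusGenotype(pair) for pair in key)
        ): m / total
        for key, m in mass.items()
    }
    return GenotypeDistribution(donor_id, out, unnormalized_mass=total)


def trs(dist: GenotypeDistribution) -> float:
    """Typing resolution score: sum of squared candidate probabilities.

    A Simpson-type concentration index on the renormalized genotype
    distribution — 1 for a single candidate, 1/k for k equiprobable
    candidates, low values meaning highly ambiguous imputation.
    """
    if dist.unexplainable:
        raise ValueError("TRS undefined for an empty distribution")
    return float(sum(p * p for p in dist.candidates.values()))


def impute_top(dist: GenotypeDistribution) -> ImputationResult:
    """The highest-probability genotype call with its TRS.

    Exact probability ties are broken by lexicographic order of the
    genotype's canonical string (deterministic across runs).
    """
    if dist.unexplainable:
        return ImputationResult(
            donor_id=dist.donor_id,
            top=None,
            top_probability=0.0,
            trs=0.0,
            n_candidates=0,
            unexplainable=True,
        )
    best_p = max(dist.candidates.values())
    ties = [g for g, p in dist.candidates.items() if p == best_p]
    top = min(ties, key=str)
    return ImputationResult(
        donor_id=dist.donor_id,
        top=top,
        top_probability=best_p,
        trs=trs(dist),
        n_candidates=len(dist.candidates),
        tie_broken=len(ties) > 1,
    )


def project_locus(
    obj: GenotypeDistribution | MultiLocusUnphasedGenotype, locus: str
):
    """Marginalize a genotype or distribution to a single locus.

    For a distribution, candidates identical at the locus are merged,
    so the marginal can only be less ambiguous than the joint.
    """
    if isinstance(obj, MultiLocusUnphasedGenotype):
        return obj.at(locus)
    if locus not in (obj.candidates and next(iter(obj.candidates)).loci or ()):
        raise KeyError(locus)
    out: dict[LocusGenotype, float] = {}
    for g, p in obj.candidates.items():
        lg = g.at(locus)
        out[lg] = out.get(lg, 0.0) + p
    return out
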