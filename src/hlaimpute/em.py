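"""Haplotype frequency estimation from ambiguous unphased genotypes.

The likelihood treats each donor's phased genotype as latent: an
observed (possibly ambiguous) typing is explained by every unordered
haplotype pair that is locus-wise consistent with it, and under
Hardy-Weinberg equilibrium a pair (h_i, h_j) has prior probability
2 f_i f_j (i != j) or f_i^2.  The EM algorithm alternates between
weighting each donor's explanations by their current probability and
re-estimating frequencies from the expected haplotype counts; the
log-likelihood is non-decreasing at every iteration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import (
    LOCI,
    Allele,
    AmbiguousMultiLocusTyping,
    LocusGenotype,
    MultiLocusUnphasedGenotype,
    parse_allele,
)


@dataclass(frozen=True, slots=True, order=True)
class Haplotype:
    """One two-field allele per locus, in canonical locus order."""

    alleles: tuple[Allele, ...]

    def __post_init__(self) -> None:
        order = {l: i for i, l in enumerate(LOCI)}
        loci = [a.locus for a in self.alleles]
        if len(set(loci)) != len(loci) or any(l not in order for l in loci):
            raise ValueError(f"invalid haplotype loci: {loci}")
        ordered = tuple(sorted(self.alleles, key=lambda a: order[a.locus]))
        object.__setattr__(self, "alleles", ordered)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(a.locus for a in self.alleles)

    def at(self, locus: str) -> Allele:
        for a in self.alleles:
            if a.locus == locus:
                return a
        raise KeyError(locus)

    def restrict(self, loci) -> "Haplotype":
        keep = set(loci)
        return Haplotype(tuple(a for a in self.alleles if a.locus in keep))

    def __str__(self) -> str:
        return "~".join(str(a) for a in self.alleles)


def parse_haplotype(text: str) -> Haplotype:
    return Haplotype(tuple(parse_allele(t) for t in text.strip().split("~")))


def unphase(h1: Haplotype, h2: Haplotype) -> MultiLocusUnphasedGenotype:
    """Collapse a phased haplotype pair into its unphased genotype."""
    if h1.loci != h2.loci:
        raise ValueError("haplotypes cover different loci")
    return MultiLocusUnphasedGenotype(
        tuple(
            LocusGenotype((a1, a2)) for a1, a2 in zip(h1.alleles, h2.alleles)
        )
    )


class HaplotypeFrequencyTable:
    """Haplotypes with population frequencies; the imputation prior.

    Frequencies are normalized to sum to 1 on construction.  The table
    is ordered by descending frequency.
    """

    def __init__(self, haplotypes, frequencies, normalize: bool = True):
        haplotypes = list(haplotypes)
        freqs = np.asarray(frequencies, dtype=float)
        if len(haplotypes) != freqs.size:
            raise ValueError("haplotype/frequency length mismatch")
        if len(set(haplotypes)) != len(haplotypes):
            raise ValueError("duplicate haplotypes in table")
        if freqs.size == 0:
            raise ValueError("empty frequency table")
        if np.any(freqs < 0):
            raise ValueError("negative frequency")
        total = freqs.sum()
        if total <= 0:
            raise ValueError("frequencies sum to zero")
        if normalize:
            freqs = freqs / total
        order = np.argsort(-freqs, kind="stable")
        self.haplotypes: tuple[Haplotype, ...] = tuple(haplotypes[i] for i in order)
        self.frequencies: np.ndarray = freqs[order]
        self.loci: tuple[str, ...] = self.haplotypes[0].loci
        if any(h.loci != self.loci for h in self.haplotypes):
            raise ValueError("haplotypes cover inconsistent locus sets")
        self._index = {h: i for i, h in enumerate(self.haplotypes)}

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __contains__(self, h: Haplotype) -> bool:
        return h in self._index

    def frequency(self, h: Haplotype) -> float:
        i = self._index.get(h)
        return 0.0 if i is None else float(self.frequencies[i])

    def items(self):
        for h, f in zip(self.haplotypes, self.frequencies):
            yield h, float(f)

    def allele_universe(self, locus: str) -> frozenset[Allele]:
        """All two-field alleles the table knows at one locus."""
        return frozenset(h.at(locus) for h in self.haplotypes)

    def universes(self) -> dict[str, frozenset[Allele]]:
        return {l: self.allele_universe(l) for l in self.loci}

    def marginalize(self, loci) -> "HaplotypeFrequencyTable":
        """Sum frequencies of haplotypes sharing the same sub-haplotype."""
        loci = tuple(l for l in self.loci if l in set(loci))
        if not loci:
            raise ValueError("empty locus subset")
        acc: dict[Haplotype, float] = {}
        for h, f in self.items():
            sub = h.restrict(loci)
            acc[sub] = acc.get(sub, 0.0) + f
        return HaplotypeFrequencyTable(list(acc.keys()), list(acc.values()))

    def drop(self, withheld) -> "HaplotypeFrequencyTable":
        withheld = set(withheld)
        keep = [(h, f) for h, f in self.items() if h not in withheld]
        if not keep:
            raise ValueError("cannot withhold every haplotype")
        return HaplotypeFrequencyTable([h for h, _ in keep], [f for _, f in keep])


def allele_frequencies(table: HaplotypeFrequencyTable, locus: str) -> dict[Allele, float]:
    """Marginal allele frequencies at one locus (sum over haplotypes)."""
    if locus not in table.loci:
        raise KeyError(f"locus {locus} not in table locus set {table.loci}")
    out: dict[Allele, float] = {}
    for h, f in table.items():
        a = h.at(locus)
        out[a] = out.get(a, 0.0) + f
    return out


# ---------------------------------------------------------------------------
# Explanation enumeration


@dataclass(frozen=True)
class ExplanationSet:
    """All unordered haplotype pairs consistent with one donor's typing."""

    donor_id: str
    pairs: tuple[tuple[Haplotype, Haplotype], ...]

    @property
    def unexplainable(self) -> bool:
        return not self.pairs

    def haplotypes(self) -> set[Haplotype]:
        return {h for pair in self.pairs for h in pair}


def _slot_assignment_ok(
    h1: Haplotype, h2: Haplotype, typing: AmbiguousMultiLocusTyping
) -> bool:
    for s1, s2 in typing.slots:
        a = h1.at(s1.locus)
        b = h2.at(s1.locus)
        if not ((a in s1 and b in s2) or (a in s2 and b in s1)):
            return False
    return True


def enumerate_explanations(
    typing: AmbiguousMultiLocusTyping,
    universe,
    donor_id: str = "",
) -> ExplanationSet:
    """All unordered pairs from ``universe`` consistent with the typing.

    A pair is consistent when at every locus its unordered allele pair
    uses each of the typing's two observed slots exactly once.
    """
    # Pre-filter: a haplotype can participate only if every locus allele
    # occurs in at least one slot.
    unions = {p[0].locus: p[0].candidates | p[1].candidates for p in typing.slots}
    loci = typing.loci
    cand = [
        h for h in universe
        if all(h.at(l) in unions[l] for l in loci)
    ]
    cand.sort()
    pairs = []
    for i, h1 in enumerate(cand):
        for h2 in cand[i:]:
            if _slot_assignment_ok(h1, h2, typing):
                pairs.append((h1, h2))
    return ExplanationSet(donor_id, tuple(pairs))


def candidate_haplotypes(typing: AmbiguousMultiLocusTyping):
    """All haplotypes buildable by choosing, at each locus, one allele
    from either observed slot — the donor's own explanation universe."""
    unions = [sorted(p[0].candidates | p[1].candidates) for p in typing.slots]
    for combo in itertools.product(*unions):
        yield Haplotype(tuple(combo))


def default_universe(typings) -> set[Haplotype]:
    """Union over donors of per-donor explanation haplotypes.

    The full Cartesian product over all donors' allele sets is
    intractable at five loci; haplotypes that no single donor could
    carry cannot gain EM mass from this data anyway.
    """
    out: set[Haplotype] = set()
    for t in typings:
        out.update(candidate_haplotypes(t))
    return out


# ---------------------------------------------------------------------------
# EM estimation


@dataclass
class EMResult:
    table: HaplotypeFrequencyTable
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    n_excluded: int = 0


def em_estimate(
    typings,
    universe=None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    prune: float = 1e-12,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies by EM.

    ``typings`` is a sequence of :class:`AmbiguousMultiLocusTyping`
    (or ``(donor_id, typing)`` pairs).  Donors with no explanation in
    the universe are excluded and counted in ``n_excluded``.

    Initialization is uniform over haplotypes appearing in at least one
    explanation; ``seed`` instead draws a random Dirichlet start for
    multi-start exploration.
    """
    pairs_in = []
    for i, t in enumerate(typings):
        if isinstance(t, tuple):
            pairs_in.append((str(t[0]), t[1]))
        else:
            pairs_in.append((str(i), t))
    if universe is None:
        universe = default_universe(t for _, t in pairs_in)
    universe = sorted(set(universe))

    explanations = [
        enumerate_explanations(t, universe, donor_id=d) for d, t in pairs_in
    ]
    used = sorted({h for e in explanations for h in e.haplotypes()})
    n_excluded = sum(1 for e in explanations if e.unexplainable)
    explanations = [e for e in explanations if not e.unexplainable]
    if not explanations:
        raise ValueError("no donor has any explanation in the universe")

    idx = {h: k for k, h in enumerate(used)}
    K = len(used)
    # Group donors sharing the same explanation set: the E-step weights
    # are identical within a group, so one donor's work covers all.
    grouped: dict[tuple, float] = {}
    for e in explanations:
        key = tuple(sorted((idx[a], idx[b]) for a, b in e.pairs))
        grouped[key] = grouped.get(key, 0.0) + 1.0
    donors = []
    for key, mult in grouped.items():
        ii = np.array([p[0] for p in key], dtype=np.intp)
        jj = np.array([p[1] for p in key], dtype=np.intp)
        coef = np.where(ii == jj, 1.0, 2.0)
        donors.append((ii, jj, coef, mult))
    N = len(explanations)

    if seed is None:
        f = np.full(K, 1.0 / K)
    else:
        f = np.random.default_rng(seed).dirichlet(np.ones(K))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(K)
        loglik = 0.0
        for ii, jj, coef, mult in donors:
            p = coef * f[ii] * f[jj]
            tot = p.sum()
            if tot <= 0.0:
                # All current mass outside this donor's explanations;
                # fall back to uniform responsibility.
                w = np.full(p.size, mult / p.size)
                loglik += -np.inf
            else:
                w = mult * p / tot
                loglik += mult * float(np.log(tot))
            np.add.at(counts, ii, w)
            np.add.at(counts, jj, w)
        f = counts / (2.0 * N)
        trace.append(loglik)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    keep = f > prune
    if not np.any(keep):
        keep = f == f.max()
    table = HaplotypeFrequencyTable(
        [h for h, k in zip(used, keep) if k], f[keep]
    )
    return EMResult(
        table=table,
        log_likelihood=trace[-1],
        n_iterations=it,
        converged=converged,
        loglik_trace=trace,
        n_excluded=n_excluded,
    )


def log_likelihood(table: HaplotypeFrequencyTable, typings) -> float:
    """Observed-data log-likelihood of typings under a frequency table."""
    total = 0.0
    universe = set(table.haplotypes)
    for t in typings:
        e = enumerate_explanations(t, universe)
        mass = 0.0
        for h1, h2 in e.pairs:
            f1, f2 = table.frequency(h1), table.frequency(h2)
            mass += (f1 * f2) if h1 == h2 else (2.0 * f1 * f2)
        total += np.log(mass) if mass > 0 else -np.inf
    return float(total)
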