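"""Core HLA nomenclature data model.

Alleles are represented at up to first-two-field resolution
(allele group + protein designator, e.g. ``A*01:01``).  Ambiguous
typings — first-field groups (``A*01``) or multiple-allele codes
(``A*01:AB``) — expand to candidate sets against the allele universe
of a haplotype frequency table.  G-group standardization maps alleles
with identical peptide-binding-domain exon sequences onto a single
representative so that downstream genotype comparisons do not penalize
distinctions that are invisible to matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: Canonical locus order used everywhere (haplotype strings, file columns).
LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1")

CLASS_I: tuple[str, ...] = ("A", "B", "C")
CLASS_II: tuple[str, ...] = ("DRB1", "DQB1")


class AlleleParseError(ValueError):
    """Raised when an allele string does not follow the supported grammar."""


class UnexplainableTypingError(ValueError):
    """A typing token expands to no candidate allele in the universe."""

    def __init__(self, locus: str, token: str, message: str | None = None):
        self.locus = locus
        self.token = token
        super().__init__(message or f"unexplainable typing at {locus}: {token!r}")


_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<f1>\d+)(?::(?P<f2>\d+))?(?P<g>G)?$"
)


@dataclass(frozen=True, slots=True, order=True)
class Allele:
    """A first-field or first-two-field HLA allele name.

    ``field2 is None`` denotes first-field (allele-group) resolution.
    ``g_suffix`` marks a G-group representative name such as ``B*07:02G``.
    """

    locus: str
    field1: str
    field2: str | None = None
    g_suffix: bool = False

    def __post_init__(self) -> None:
        if not self.field1:
            raise AlleleParseError("empty allele-group field")

    @property
    def is_two_field(self) -> bool:
        return self.field2 is not None

    @property
    def group(self) -> "Allele":
        """The first-field allele group this allele belongs to."""
        return Allele(self.locus, self.field1)

    def __str__(self) -> str:
        s = f"{self.locus}*{self.field1}"
        if self.field2 is not None:
            s += f":{self.field2}"
        if self.g_suffix:
            s += "G"
        return s


def parse_allele(text: str, allow_g: bool = False) -> Allele:
    """Parse ``LOCUS*F1[:F2][G]`` into an :class:`Allele`.

    The trailing ``G`` (a G-group name) is rejected unless ``allow_g``
    is set, since plain typing files should not contain group names.
    """
    m = _ALLELE_RE.match(text.strip())
    if not m:
        raise AlleleParseError(f"malformed allele string: {text!r}")
    if m.group("g") and not allow_g:
        raise AlleleParseError(
            f"G-suffixed name {text!r} not accepted (enable the G dialect)"
        )
    return Allele(
        locus=m.group("locus"),
        field1=m.group("f1"),
        field2=m.group("f2"),
        g_suffix=bool(m.group("g")),
    )


def _allele_sort_key(a: Allele) -> tuple:
    return (a.locus, a.field1, a.field2 or "", a.g_suffix)


@dataclass(frozen=True, slots=True)
class AlleleSet:
    """The candidate two-field alleles an observed typing token expands to."""

    locus: str
    candidates: frozenset[Allele]
    origin: str  # "explicit" | "first_field_mask" | "mac_code"

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("AlleleSet must be non-empty")
        if any(a.locus != self.locus for a in self.candidates):
            raise ValueError("AlleleSet candidates must share the locus")

    def __len__(self) -> int:
        return len(self.candidates)

    def __contains__(self, a: Allele) -> bool:
        return a in self.candidates


@dataclass(frozen=True, slots=True)
class LocusGenotype:
    """Unordered pair of two-field alleles at one locus.

    The pair is stored sorted so equality is order-free; homozygous
    pairs are allowed.
    """

    alleles: tuple[Allele, Allele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a.locus != b.locus:
            raise ValueError("both alleles of a genotype must share the locus")
        if _allele_sort_key(a) > _allele_sort_key(b):
            object.__setattr__(self, "alleles", (b, a))

    @property
    def locus(self) -> str:
        return self.alleles[0].locus

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def __str__(self) -> str:
        return f"{self.alleles[0]}+{self.alleles[1]}"


@dataclass(frozen=True, slots=True)
class MultiLocusUnphasedGenotype:
    """One :class:`LocusGenotype` per locus, in canonical locus order."""

    genotypes: tuple[LocusGenotype, ...]

    def __post_init__(self) -> None:
        loci = [g.locus for g in self.genotypes]
        order = {l: i for i, l in enumerate(LOCI)}
        unknown = [l for l in loci if l not in order]
        if unknown:
            raise ValueError(f"unknown loci: {unknown}")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus in multi-locus genotype")
        ordered = tuple(sorted(self.genotypes, key=lambda g: order[g.locus]))
        object.__setattr__(self, "genotypes", ordered)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(g.locus for g in self.genotypes)

    def at(self, locus: str) -> LocusGenotype:
        for g in self.genotypes:
            if g.locus == locus:
                return g
        raise KeyError(locus)

    def restrict(self, loci: Iterable[str]) -> "MultiLocusUnphasedGenotype":
        keep = set(loci)
        return MultiLocusUnphasedGenotype(
            tuple(g for g in self.genotypes if g.locus in keep)
        )

    def __str__(self) -> str:
        return "^".join(str(g) for g in self.genotypes)


@dataclass(frozen=True, slots=True)
class AmbiguousMultiLocusTyping:
    """Per locus, the unordered pair of candidate sets an observed typing gave."""

    slots: tuple[tuple[AlleleSet, AlleleSet], ...]

    def __post_init__(self) -> None:
        order = {l: i for i, l in enumerate(LOCI)}
        loci = [pair[0].locus for pair in self.slots]
        for s1, s2 in self.slots:
            if s1.locus != s2.locus:
                raise ValueError("slot pair must share the locus")
            if s1.locus not in order:
                raise ValueError(f"unknown locus {s1.locus}")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus")
        ordered = tuple(sorted(self.slots, key=lambda p: order[p[0].locus]))
        object.__setattr__(self, "slots", ordered)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(p[0].locus for p in self.slots)

    def at(self, locus: str) -> tuple[AlleleSet, AlleleSet]:
        for pair in self.slots:
            if pair[0].locus == locus:
                return pair
        raise KeyError(locus)

    def restrict(self, loci: Iterable[str]) -> "AmbiguousMultiLocusTyping":
        keep = set(loci)
        return AmbiguousMultiLocusTyping(
            tuple(p for p in self.slots if p[0].locus in keep)
        )

    def contains(self, genotype: MultiLocusUnphasedGenotype) -> bool:
        """True when the genotype is consistent with this typing
        (each observed slot accounts for one allele at every locus)."""
        for g in genotype.genotypes:
            s1, s2 = self.at(g.locus)
            a, b = g.alleles
            if not ((a in s1 and b in s2) or (a in s2 and b in s1)):
                return False
        return True


# ---------------------------------------------------------------------------
# Ambiguity expansion


_MAC_RE = re.compile(r"^(?P<locus>[A-Z0-9]+)\*(?P<f1>\d+):(?P<code>[A-Z]{2,})$")


@dataclass(frozen=True)
class MACTable:
    """Multiple-allele-code expansions (code -> candidate designators).

    Expansion items are either bare protein designators (``"02"``,
    applied to the token's locus and allele group), locus-less two-field
    names (``"01:03"``) or full allele names (``"B*07:02"``).
    """

    entries: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for code, items in self.entries.items():
            if len(items) < 2:
                raise ValueError(f"MAC code {code!r} must expand to >=2 candidates")

    def expand(self, locus: str, field1: str, code: str) -> list[Allele]:
        items = self.entries.get(code)
        if items is None:
            raise UnexplainableTypingError(
                locus, f"{locus}*{field1}:{code}", f"unknown MAC code {code!r}"
            )
        out = []
        for item in items:
            if "*" in item:
                out.append(parse_allele(item))
            elif ":" in item:
                f1, f2 = item.split(":")
                out.append(Allele(locus, f1, f2))
            else:
                out.append(Allele(locus, field1, item))
        return out


def expand_typing(
    locus: str,
    token: str,
    mac: MACTable | None,
    universe: frozenset[Allele] | set[Allele],
) -> AlleleSet:
    """Expand one observed typing token into its candidate allele set.

    ``universe`` is the set of two-field alleles the frequency table
    knows at this locus.  Explicit two-field tokens stay singletons
    (even off-universe — the donor then simply has no haplotype
    explanation); group and MAC tokens are resolved against the
    universe and an empty result is an unexplainable-typing error.
    """
    m = _MAC_RE.match(token.strip())
    if m is not None:
        if m.group("locus") != locus:
            raise AlleleParseError(f"token {token!r} does not belong to locus {locus}")
        if mac is None:
            raise UnexplainableTypingError(locus, token, "no MAC table supplied")
        cand = [a for a in mac.expand(locus, m.group("f1"), m.group("code"))
                if a in universe]
        if not cand:
            raise UnexplainableTypingError(locus, token)
        return AlleleSet(locus, frozenset(cand), "mac_code")

    allele = parse_allele(token)
    if allele.locus != locus:
        raise AlleleParseError(f"token {token!r} does not belong to locus {locus}")
    if allele.is_two_field:
        return AlleleSet(locus, frozenset({allele}), "explicit")
    cand = frozenset(a for a in universe if a.field1 == allele.field1)
    if not cand:
        raise UnexplainableTypingError(locus, token)
    return AlleleSet(locus, cand, "first_field_mask")


# ---------------------------------------------------------------------------
# G-group standardization


@dataclass(frozen=True)
class GGroupMap:
    """Mapping from two-field alleles to their G-group representative.

    Alleles absent from the map standardize to themselves: the source
    lists only allele groups that are actually ambiguous at the
    peptide-binding-domain exons.
    """

    entries: Mapping[Allele, Allele]

    def standardize_allele(self, a: Allele) -> Allele:
        return self.entries.get(a, a)

    def standardize_genotype(self, g: LocusGenotype) -> LocusGenotype:
        return LocusGenotype(tuple(self.standardize_allele(a) for a in g.alleles))

    def standardize(
        self, genotype: MultiLocusUnphasedGenotype
    ) -> MultiLocusUnphasedGenotype:
        return MultiLocusUnphasedGenotype(
            tuple(self.standardize_genotype(g) for g in genotype.genotypes)
        )

    def unmapped(self, alleles: Iterable[Allele]) -> list[Allele]:
        """Completeness report: alleles that would pass through unchanged."""
        return sorted(
            {a for a in alleles if a not in self.entries}, key=_allele_sort_key
        )


IDENTITY_GGROUPS = GGroupMap(entries={})


def sort_alleles(alleles: Iterable[Allele]) -> list[Allele]:
    return sorted(alleles, key=_allele_sort_key)
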