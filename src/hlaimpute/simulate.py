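"""Synthetic donor populations with the statistical structure the
validation design assumes.

A haplotype pool with a skewed (Dirichlet) frequency spectrum stands in
for a registry frequency table; diploid donors are drawn by random
union of haplotypes (Hardy-Weinberg equilibrium), optionally with
whole-haplotype inbreeding; typing ambiguity is created by masking
two-field alleles to their first-field allele group or to multiple-
allele codes; and rare alleles or haplotypes can be withheld from the
"published" table to emulate a sample whose variants were never
reported to a registry.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .em import Haplotype, HaplotypeFrequencyTable, unphase
from .model import (
    LOCI,
    Allele,
    AlleleSet,
    AmbiguousMultiLocusTyping,
    MACTable,
    MultiLocusUnphasedGenotype,
    expand_typing,
)


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic population.

    Defaults mirror a desk-scale donor validation study: 144 donors
    typed at five loci, a skewed pool of 120 five-locus haplotypes
    (symmetric Dirichlet with concentration 0.2), first-field masking,
    and no departures from HWE.
    """

    loci: tuple[str, ...] = LOCI
    alleles_per_locus: int = 8
    n_haplotypes: int = 120
    concentration: float = 0.2
    n_donors: int = 144
    inbreeding_f: float = 0.0
    mask_scheme: str = "first_field"  # first_field | mac_like | none
    groups_per_locus: int = 4
    mac_subset_size: int = 2
    novel_haplotype_rate: float = 0.0
    rare_allele_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        if any(l not in LOCI for l in self.loci) or not self.loci:
            raise ValueError(f"loci must be a subset of {LOCI}")
        if self.alleles_per_locus < 1 or self.n_donors < 1:
            raise ValueError("alleles_per_locus and n_donors must be positive")
        if self.n_haplotypes < 1 or self.n_haplotypes > self.alleles_per_locus ** len(self.loci):
            raise ValueError(
                "n_haplotypes must be in [1, alleles_per_locus ** n_loci]"
            )
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for name in ("inbreeding_f", "novel_haplotype_rate", "rare_allele_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mask_scheme not in ("first_field", "mac_like", "none"):
            raise ValueError(f"unknown mask scheme {self.mask_scheme!r}")
        if not 1 <= self.groups_per_locus <= self.alleles_per_locus:
            raise ValueError("groups_per_locus must be in [1, alleles_per_locus]")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self) | {"loci": list(self.loci)}, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        d["loci"] = tuple(d.get("loci", LOCI))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class SyntheticPopulation:
    config: SimConfig
    generating_table: HaplotypeFrequencyTable
    published_table: HaplotypeFrequencyTable
    withheld: set[Haplotype]
    phased_truth: list[tuple[str, tuple[Haplotype, Haplotype]]]
    truth: list[tuple[str, MultiLocusUnphasedGenotype]]
    ambiguous_tokens: list[tuple[str, dict[str, tuple[str, str]]]]
    ambiguous: list[tuple[str, AmbiguousMultiLocusTyping]]
    mac_table: MACTable | None = None
    rare_injected: set[str] = field(default_factory=set)


def _allele_name(locus: str, index: int, per_group: int) -> Allele:
    group = index // per_group
    member = index % per_group
    return Allele(locus, f"{group + 1:02d}", f"{member + 1:02d}")


def locus_alleles(config: SimConfig, locus: str) -> list[Allele]:
    """The two-field alleles of one locus, binned consecutively into
    ``groups_per_locus`` first-field groups."""
    per_group = math.ceil(config.alleles_per_locus / config.groups_per_locus)
    return [
        _allele_name(locus, i, per_group) for i in range(config.alleles_per_locus)
    ]


def make_haplotype_pool(config: SimConfig) -> HaplotypeFrequencyTable:
    """Draw the generating haplotype pool and its frequency spectrum.

    ``n_haplotypes`` distinct haplotypes are chosen uniformly from the
    Cartesian product of per-locus alleles; frequencies come from a
    symmetric Dirichlet(concentration) sorted descending, which for
    small concentration yields the steeply skewed spectra typical of
    HLA haplotype tables.
    """
    rng = np.random.default_rng(config.seed)
    alleles = {l: locus_alleles(config, l) for l in config.loci}
    space = config.alleles_per_locus ** len(config.loci)
    if config.n_haplotypes == space:
        combos = list(itertools.product(*(alleles[l] for l in config.loci)))
    else:
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < config.n_haplotypes:
            draw = tuple(
                int(x)
                for x in rng.integers(0, config.alleles_per_locus, len(config.loci))
            )
            chosen.add(draw)
        combos = [
            tuple(alleles[l][i] for l, i in zip(config.loci, key))
            for key in sorted(chosen)
        ]
    haps = [Haplotype(c) for c in combos]
    freqs = np.sort(rng.dirichlet(np.full(len(haps), config.concentration)))[::-1]
    return HaplotypeFrequencyTable(haps, freqs)


def sample_population(
    table: HaplotypeFrequencyTable,
    n_donors: int,
    inbreeding_f: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, tuple[Haplotype, Haplotype]]]:
    """Draw phased donors: with probability ``inbreeding_f`` the two
    haplotypes are identical by descent (one draw), otherwise two
    independent draws — exactly HWE random union at F = 0."""
    rng = np.random.default_rng(seed)
    n = len(table)
    width = max(4, len(str(n_donors)))
    out = []
    first = rng.choice(n, size=n_donors, p=table.frequencies)
    second = rng.choice(n, size=n_donors, p=table.frequencies)
    ibd = rng.random(n_donors) < inbreeding_f
    for d in range(n_donors):
        i = int(first[d])
        j = i if ibd[d] else int(second[d])
        out.append(
            (f"D{d + 1:0{width}d}", (table.haplotypes[i], table.haplotypes[j]))
        )
    return out


def _mac_code(counter: itertools.count) -> str:
    # AA, AB, ... excluding short real-looking codes is unnecessary here.
    n = next(counter)
    letters = ""
    for _ in range(2):
        letters = chr(ord("A") + n % 26) + letters
        n //= 26
    return letters


def mask_population(
    phased: list[tuple[str, tuple[Haplotype, Haplotype]]],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[tuple[str, dict[str, tuple[str, str]]]], MACTable | None]:
    """Produce observed (ambiguous) typing tokens for each donor.

    ``first_field`` masks every allele to its allele-group token;
    ``mac_like`` replaces each allele by a multiple-allele code
    expanding to a random subset of its group that contains the truth;
    ``none`` passes two-field tokens through.  The truth genotype is
    contained in the expansion by construction.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    group_members: dict[tuple[str, str], list[Allele]] = {}
    for l in config.loci:
        for a in locus_alleles(config, l):
            group_members.setdefault((l, a.field1), []).append(a)

    codes: dict[frozenset[str], str] = {}
    counter = itertools.count()
    entries: dict[str, tuple[str, ...]] = {}

    def token(a: Allele) -> str:
        if config.mask_scheme == "none":
            return str(a)
        if config.mask_scheme == "first_field":
            return f"{a.locus}*{a.field1}"
        members = group_members.get((a.locus, a.field1), [a])
        others = [m for m in members if m != a]
        extra = min(config.mac_subset_size - 1, len(others))
        if extra == 0:
            return str(a)
        pick = list(rng.choice(len(others), size=extra, replace=False))
        subset = sorted({a.field2} | {others[i].field2 for i in pick})
        key = frozenset(subset)
        code = codes.get(key)
        if code is None:
            code = _mac_code(counter)
            while code in entries:
                code = _mac_code(counter)
            codes[key] = code
            entries[code] = tuple(subset)
        return f"{a.locus}*{a.field1}:{code}"

    rows = []
    for donor_id, (h1, h2) in phased:
        rows.append(
            (donor_id, {l: (token(h1.at(l)), token(h2.at(l))) for l in config.loci})
        )
    mac = MACTable(entries) if entries else None
    return rows, mac


def withhold_haplotypes(
    table: HaplotypeFrequencyTable,
    novel_haplotype_rate: float,
    seed: int = 0,
    phased: list[tuple[str, tuple[Haplotype, Haplotype]]] | None = None,
) -> tuple[HaplotypeFrequencyTable, set[Haplotype], set[str]]:
    """Remove low-frequency haplotypes from the published table.

    Haplotypes are withheld from the rare end of the spectrum until
    their cumulative frequency reaches ``rate / 2`` (a donor carries
    two haplotypes, so the expected fraction of donors carrying at
    least one withheld haplotype is about twice the withheld mass).
    Returns the renormalized published table, the withheld set, and —
    when phased donors are supplied — the ids of carriers.
    """
    if not 0.0 <= novel_haplotype_rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if novel_haplotype_rate == 0.0:
        return table, set(), set()
    target = novel_haplotype_rate / 2.0
    withheld: set[Haplotype] = set()
    cum = 0.0
    for h, f in reversed(list(table.items())):  # rarest first
        withheld.add(h)
        cum += f
        if cum >= target:
            break
    if len(withheld) >= len(table):
        raise ValueError("withholding would empty the published table")
    published = table.drop(withheld)
    carriers = set()
    if phased is not None:
        carriers = {
            d for d, (h1, h2) in phased if h1 in withheld or h2 in withheld
        }
    return published, withheld, carriers


def _inject_rare_alleles(phased, config: SimConfig):
    """Replace one allele of one haplotype with a novel allele (absent
    from the pool) in a random fraction of donors."""
    if config.rare_allele_rate == 0.0:
        return phased, set()
    rng = np.random.default_rng(config.seed + 2)
    injected = set()
    out = []
    for donor_id, (h1, h2) in phased:
        if rng.random() < config.rare_allele_rate:
            locus = config.loci[int(rng.integers(len(config.loci)))]
            which = int(rng.integers(2))
            rare = Allele(locus, "99", f"{1 + int(rng.integers(99)):02d}")
            target = [h1, h2][which]
            alleles = tuple(
                rare if a.locus == locus else a for a in target.alleles
            )
            new = Haplotype(alleles)
            h1, h2 = (new, h2) if which == 0 else (h1, new)
            injected.add(donor_id)
        out.append((donor_id, (h1, h2)))
    return out, injected


def expand_tokens(
    token_rows,
    table: HaplotypeFrequencyTable,
    mac: MACTable | None,
    truths: list[tuple[str, MultiLocusUnphasedGenotype]] | None = None,
) -> list[tuple[str, AmbiguousMultiLocusTyping]]:
    """Expand raw typing tokens against a table's allele universes.

    When aligned ``truths`` are supplied, each donor's own true alleles
    are added to the expansion universe so the resulting typing always
    contains the truth genotype even when the donor carries an allele
    the frequency table has never seen (the imputation step will then
    flag such a donor unexplainable, not the typing step).
    """
    universes = table.universes()
    truth_map = dict(truths) if truths else {}
    out = []
    for donor_id, per_locus in token_rows:
        truth = truth_map.get(donor_id)
        slots = []
        for l, (t1, t2) in per_locus.items():
            uni = universes[l]
            if truth is not None:
                uni = uni | set(truth.at(l).alleles)
            slots.append(
                (
                    expand_typing(l, t1, mac, uni),
                    expand_typing(l, t2, mac, uni),
                )
            )
        out.append((donor_id, AmbiguousMultiLocusTyping(tuple(slots))))
    return out


def generate(config: SimConfig) -> SyntheticPopulation:
    """Run the whole generator: pool, donors, rare-allele injection,
    masking, and withholding.  Deterministic given the config."""
    table = make_haplotype_pool(config)
    phased = sample_population(
        table, config.n_donors, config.inbreeding_f, seed=config.seed
    )
    phased, injected = _inject_rare_alleles(phased, config)
    truth = [(d, unphase(h1, h2)) for d, (h1, h2) in phased]
    token_rows, mac = mask_population(phased, config)
    published, withheld, _ = withhold_haplotypes(
        table, config.novel_haplotype_rate, seed=config.seed, phased=phased
    )
    # Expansion uses the *generating* universe so truth tokens always
    # expand; explanation against the published table happens downstream.
    ambiguous = expand_tokens(token_rows, table, mac, truths=truth)
    return SyntheticPopulation(
        config=config,
        generating_table=table,
        published_table=published,
        withheld=withheld,
        phased_truth=phased,
        truth=truth,
        ambiguous_tokens=token_rows,
        ambiguous=ambiguous,
        mac_table=mac,
        rare_injected=injected,
    )
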