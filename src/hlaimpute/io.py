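"""Readers and writers for the plain-text exchange formats.

* Haplotype frequency tables: tab-separated ``haplotype`` /
  ``frequency`` (optional ``rank``) with ``~``-joined allele names.
* Donor genotype tables: tab-separated, one donor per row, an ``id``
  column then two typing tokens per locus in canonical order; an empty
  cell marks an untyped locus.
* G-group maps in the ``hla_nom_g`` dialect: ``#`` comments, data lines
  ``LOCUS*;ALLELE1/ALLELE2/...;GROUP`` where an empty third field
  defines no group.
* Multiple-allele-code tables: two tab-separated columns, the code and
  a ``/``-separated expansion list.
* Reference population allele-group frequencies: tab-separated
  ``locus``, ``allele_group``, ``frequency``, ``n``.
"""

from __future__ import annotations

import os
from typing import Iterable

from .em import HaplotypeFrequencyTable, parse_haplotype
from .model import (
    Allele,
    GGroupMap,
    LocusGenotype,
    MACTable,
    MultiLocusUnphasedGenotype,
    parse_allele,
)


# ---------------------------------------------------------------------------
# Frequency tables


def write_frequency_table(table: HaplotypeFrequencyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tfrequency\trank\n")
        for rank, (h, f) in enumerate(table.items(), start=1):
            fh.write(f"{h}\t{f:.12g}\t{rank}\n")


def read_frequency_table(path) -> HaplotypeFrequencyTable:
    haps, freqs = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            hcol = header.index("haplotype")
            fcol = header.index("frequency")
        except ValueError as e:
            raise ValueError(f"{path}: missing haplotype/frequency columns") from e
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            haps.append(parse_haplotype(parts[hcol]))
            freqs.append(float(parts[fcol]))
    return HaplotypeFrequencyTable(haps, freqs)


# ---------------------------------------------------------------------------
# Donor genotype / typing tables


def write_genotype_table(rows, loci, path) -> None:
    """``rows`` is ``(donor_id, {locus: (tok1, tok2)})`` or
    ``(donor_id, MultiLocusUnphasedGenotype)``."""
    with open(path, "w") as fh:
        cols = ["id"]
        for l in loci:
            cols += [f"{l}.1", f"{l}.2"]
        fh.write("\t".join(cols) + "\n")
        for donor_id, data in rows:
            cells = [str(donor_id)]
            for l in loci:
                if isinstance(data, MultiLocusUnphasedGenotype):
                    if l in data.loci:
                        a, b = data.at(l).alleles
                        cells += [str(a), str(b)]
                    else:
                        cells += ["", ""]
                else:
                    t1, t2 = data.get(l, ("", ""))
                    cells += [t1, t2]
            fh.write("\t".join(cells) + "\n")


def read_typing_tokens(path) -> tuple[list[tuple[str, dict]], tuple[str, ...]]:
    """Read raw typing tokens; returns (rows, loci)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id":
            raise ValueError(f"{path}: first column must be 'id'")
        loci = []
        for c in header[1::2]:
            loci.append(c.rsplit(".", 1)[0])
        rows = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            donor_id = parts[0]
            per_locus = {}
            for k, l in enumerate(loci):
                t1 = parts[1 + 2 * k] if len(parts) > 1 + 2 * k else ""
                t2 = parts[2 + 2 * k] if len(parts) > 2 + 2 * k else ""
                if t1 and t2:
                    per_locus[l] = (t1, t2)
            rows.append((donor_id, per_locus))
    return rows, tuple(loci)


def read_truth_genotypes(path) -> list[tuple[str, MultiLocusUnphasedGenotype]]:
    """Read unambiguous two-field genotype tables."""
    rows, _ = read_typing_tokens(path)
    out = []
    for donor_id, per_locus in rows:
        gts = []
        for l, (t1, t2) in per_locus.items():
            a, b = parse_allele(t1), parse_allele(t2)
            if not (a.is_two_field and b.is_two_field):
                raise ValueError(
                    f"{path}: donor {donor_id} locus {l} is not two-field"
                )
            gts.append(LocusGenotype((a, b)))
        out.append((donor_id, MultiLocusUnphasedGenotype(tuple(gts))))
    return out


# ---------------------------------------------------------------------------
# G-group map (hla_nom_g dialect)


def read_ggroup_map(path) -> GGroupMap:
    """Parse the ``hla_nom_g`` dialect into a two-field G-group map.

    Every allele listed in a group line maps to the G-group
    representative ``LOCUS*GROUPNAME`` (the group name carries the
    trailing ``G``).  Allele names with more than two fields are
    truncated to two; lines whose third field is empty define no group.
    """
    entries: dict[Allele, Allele] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(";")
            if len(parts) < 3:
                raise ValueError(f"bad hla_nom_g line: {line!r}")
            locus_tag, allele_field, group = parts[0], parts[1], parts[2]
            if not group:
                continue
            locus = locus_tag.rstrip("*")
            rep = parse_allele(f"{locus}*{group}", allow_g=True)
            for name in allele_field.split("/"):
                fields = name.split(":")
                a = Allele(locus, fields[0], fields[1] if len(fields) > 1 else None)
                entries[a] = rep
    return GGroupMap(entries)


def write_ggroup_map(ggroups: GGroupMap, path) -> None:
    by_group: dict[Allele, list[Allele]] = {}
    for a, rep in ggroups.entries.items():
        by_group.setdefault(rep, []).append(a)
    with open(path, "w") as fh:
        fh.write("# locus*;allele/allele/...;group\n")
        for rep in sorted(by_group, key=str):
            members = sorted(by_group[rep], key=str)
            names = "/".join(
                f"{a.field1}:{a.field2}" if a.field2 else a.field1 for a in members
            )
            gname = f"{rep.field1}:{rep.field2}G" if rep.g_suffix else (
                f"{rep.field1}:{rep.field2}" if rep.field2 else rep.field1
            )
            fh.write(f"{rep.locus}*;{names};{gname}\n")


# ---------------------------------------------------------------------------
# MAC table


def read_mac_table(path) -> MACTable:
    entries: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            code, expansion = line.split("\t")[:2]
            entries[code] = tuple(expansion.split("/"))
    return MACTable(entries)


def write_mac_table(mac: MACTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# code\texpansion\n")
        for code in sorted(mac.entries):
            fh.write(f"{code}\t{'/'.join(mac.entries[code])}\n")


# ---------------------------------------------------------------------------
# Reference population allele-group frequencies


def read_reference_frequencies(path):
    """Returns ({locus: {group: freq}}, {locus: n})."""
    freqs: dict[str, dict[str, float]] = {}
    ns: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = ["locus", "allele_group", "frequency", "n"]
        if header[: len(need)] != need:
            raise ValueError(f"{path}: expected columns {need}")
        for line in fh:
            if not line.strip():
                continue
            locus, group, freq, n = line.rstrip("\n").split("\t")[:4]
            freqs.setdefault(locus, {})[group] = float(freq)
            ns[locus] = int(n)
    return freqs, ns


def write_reference_frequencies(freqs, ns, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tallele_group\tfrequency\tn\n")
        for locus in freqs:
            for group, f in sorted(freqs[locus].items()):
                fh.write(f"{locus}\t{group}\t{f:.12g}\t{ns[locus]}\n")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
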