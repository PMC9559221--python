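"""HLA nomenclature model.

Alleles are named ``LOCUS*F1`` (one-field, allele group / "antigen" level,
e.g. ``A*11``) or ``LOCUS*F1:F2`` (two-field, protein level, e.g.
``A*11:01``).  A :class:`Genotype` carries up to two distinct alleles per
locus together with a provenance flag recording whether the typing was
directly performed (``typed``), estimated from population haplotype
frequencies (``imputed``), or not available.

Antigen-level mismatch counting supports the two clinically relevant views:

* ``LR3`` — one-field A/B/DRB1, the three-locus low-resolution typing still
  used by many centers (global count 0-6);
* ``HR6`` — two-field A/B/C/DRB1/DQ/DPB1, with DQ counted as one locus unit
  of alpha-beta chain pairs (global count 0-12).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AlleleParseError, MissingLocusError, ResolutionError

LOCI = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
)
CLASS_I_LOCI = frozenset({"A", "B", "C"})
CLASS_II_LOCI = frozenset(
    {"DRB1", "DRB3", "DRB4", "DRB5", "DQA1", "DQB1", "DPA1", "DPB1"}
)
#: beta-chain loci that pair with an alpha chain on DQ/DP heterodimers
ALPHA_PARTNER = {"DQB1": "DQA1", "DPB1": "DPA1"}

TYPED = "typed"
IMPUTED = "imputed"
UNAVAILABLE = "unavailable"
PROVENANCES = (TYPED, IMPUTED, UNAVAILABLE)

_ALLELE_RE = re.compile(r"^([A-Z][A-Z0-9]*)\*(\d+)(?::(\d+))?$")


@dataclass(frozen=True, order=True)
class Allele:
    """One HLA allele at one- or two-field resolution."""

    locus: str
    field1: int
    field2: int | None = None
    raw: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown HLA locus {self.locus!r}")
        if self.field1 <= 0 or (self.field2 is not None and self.field2 <= 0):
            raise AlleleParseError(f"allele fields must be positive: {self}")

    @property
    def is_two_field(self) -> bool:
        return self.field2 is not None

    @property
    def hla_class(self) -> str:
        return "I" if self.locus in CLASS_I_LOCI else "II"

    def __str__(self) -> str:
        s = f"{self.locus}*{self.field1:02d}"
        if self.field2 is not None:
            s += f":{self.field2:02d}"
        return s


def parse_allele(text: str) -> Allele:
    """Parse ``"A*11:01"`` / ``"DRB1*11"`` style nomenclature strings.

    Raises
    ------
    AlleleParseError
        If the string is malformed or names an unknown locus; the message
        carries the offending token.
    """
    token = text.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"malformed allele string {token!r}")
    locus, f1, f2 = m.group(1), int(m.group(2)), m.group(3)
    if locus not in LOCI:
        raise AlleleParseError(f"unknown HLA locus {locus!r} in {token!r}")
    return Allele(locus, f1, int(f2) if f2 is not None else None, raw=token)


def reduce_to_one_field(a: Allele) -> Allele:
    """Drop the protein field: A*11:02 -> A*11.  Idempotent."""
    if not a.is_two_field:
        return a
    return Allele(a.locus, a.field1)


def antigen_match(a: Allele, b: Allele) -> bool:
    """True iff both alleles belong to the same first-field allele group."""
    return a.locus == b.locus and a.field1 == b.field1


def allele_match(a: Allele, b: Allele) -> bool:
    """Exact two-field identity; both inputs must be two-field."""
    if not (a.is_two_field and b.is_two_field):
        raise ResolutionError(
            f"allele_match requires two-field alleles, got {a} vs {b}"
        )
    return a.locus == b.locus and a.field1 == b.field1 and a.field2 == b.field2


@dataclass(frozen=True)
class LocusTyping:
    """Up to two distinct alleles at one locus, with provenance."""

    alleles: tuple[Allele, ...]
    provenance: str = TYPED

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == UNAVAILABLE and self.alleles:
            raise ValueError("an unavailable locus must carry no alleles")
        if len(self.alleles) > 2:
            raise ValueError(f"more than two alleles at one locus: {self.alleles}")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(
                "homozygosity must be a single allele, not two equal entries"
            )


class Genotype:
    """Per-locus HLA typing of one subject.

    Homozygous loci carry a single allele.  Loci never mentioned are
    implicitly ``unavailable``.
    """

    def __init__(self, subject_id: str,
                 loci: Mapping[str, LocusTyping] | None = None) -> None:
        self.subject_id = subject_id
        self._loci: dict[str, LocusTyping] = {}
        for locus, typing in (loci or {}).items():
            self.set_locus(locus, typing)

    @classmethod
    def from_alleles(cls, subject_id: str,
                     entries: Mapping[str, tuple[Sequence[Allele], str]]
                     ) -> "Genotype":
        g = cls(subject_id)
        for locus, (alleles, provenance) in entries.items():
            g.set_locus(locus, LocusTyping(_dedupe(alleles), provenance))
        return g

    def set_locus(self, locus: str, typing: LocusTyping) -> None:
        if locus not in LOCI:
            raise AlleleParseError(f"unknown HLA locus {locus!r}")
        for a in typing.alleles:
            if a.locus != locus:
                raise ValueError(f"allele {a} stored under locus {locus}")
        self._loci[locus] = typing

    def alleles_at(self, locus: str) -> tuple[Allele, ...]:
        t = self._loci.get(locus)
        return t.alleles if t is not None else ()

    def provenance(self, locus: str) -> str:
        t = self._loci.get(locus)
        return t.provenance if t is not None else UNAVAILABLE

    def available(self, locus: str) -> bool:
        return self.provenance(locus) != UNAVAILABLE and bool(self.alleles_at(locus))

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self._loci)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        mine = {k: (frozenset(v.alleles), v.provenance)
                for k, v in self._loci.items() if v.provenance != UNAVAILABLE}
        theirs = {k: (frozenset(v.alleles), v.provenance)
                  for k, v in other._loci.items() if v.provenance != UNAVAILABLE}
        return mine == theirs

    def same_alleles(self, other: "Genotype", loci: Iterable[str]) -> bool:
        return all(
            frozenset(self.alleles_at(l)) == frozenset(other.alleles_at(l))
            for l in loci
        )

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{l}:[{'/'.join(map(str, t.alleles))}]({t.provenance[0]})"
            for l, t in sorted(self._loci.items())
        )
        return f"Genotype({self.subject_id}; {parts})"


def _dedupe(alleles: Sequence[Allele]) -> tuple[Allele, ...]:
    out: list[Allele] = []
    for a in alleles:
        if a not in out:
            out.append(a)
    return tuple(out)


# ---------------------------------------------------------------------------
# antigen/allele mismatch counting

LR3_LOCI = ("A", "B", "DRB1")
#: HR6 locus units; "DQ" is the combined DQA1+DQB1 heterodimer unit
HR6_UNITS = ("A", "B", "C", "DRB1", "DQ", "DPB1")


@dataclass(frozen=True)
class MismatchCounts:
    mode: str
    per_locus: dict
    class_i: int
    class_ii: int
    total: int


def _require(genotype: Genotype, locus: str, who: str, two_field: bool) -> None:
    if not genotype.available(locus):
        raise MissingLocusError(
            f"{who} locus {locus} is unavailable but required for mismatch counting"
        )
    if two_field and not all(a.is_two_field for a in genotype.alleles_at(locus)):
        raise ResolutionError(
            f"{who} locus {locus} must be typed at two-field resolution"
        )


def donor_dq_units(donor: Genotype) -> list[tuple[Allele, Allele]]:
    """Donor DQ heterodimer units as (beta, alpha) chain pairs.

    Donor typing is unphased; chains are paired in the order listed in the
    typing table (i-th beta with i-th alpha, a lone chain pairing with every
    partner).  Duplicate units collapse.
    """
    betas = donor.alleles_at("DQB1")
    alphas = donor.alleles_at("DQA1")
    units: list[tuple[Allele, Allele]] = []
    for i, b in enumerate(betas):
        a = alphas[min(i, len(alphas) - 1)]
        if (b, a) not in units:
            units.append((b, a))
    return units


def count_antigen_mm(recipient: Genotype, donor: Genotype,
                     mode: str) -> MismatchCounts:
    """Count donor antigens absent from the recipient, per locus and class.

    ``LR3`` compares first-field groups at A/B/DRB1; ``HR6`` compares
    two-field alleles at A/B/C/DRB1/DPB1 plus DQ heterodimer units (a donor
    DQ unit mismatches when its beta or its alpha chain is absent from the
    recipient).  Each locus contributes 0-2; homozygous donors contribute
    each distinct antigen once.
    """
    if mode == "LR3":
        per: dict[str, int] = {}
        for locus in LR3_LOCI:
            _require(recipient, locus, "recipient", two_field=False)
            _require(donor, locus, "donor", two_field=False)
            r_groups = {a.field1 for a in recipient.alleles_at(locus)}
            d_groups = {a.field1 for a in donor.alleles_at(locus)}
            per[locus] = len(d_groups - r_groups)
        class_i = per["A"] + per["B"]
        class_ii = per["DRB1"]
    elif mode == "HR6":
        per = {}
        for locus in ("A", "B", "C", "DRB1", "DPB1"):
            _require(recipient, locus, "recipient", two_field=True)
            _require(donor, locus, "donor", two_field=True)
            r = set(recipient.alleles_at(locus))
            per[locus] = len(set(donor.alleles_at(locus)) - r)
        for locus in ("DQA1", "DQB1"):
            _require(recipient, locus, "recipient", two_field=True)
            _require(donor, locus, "donor", two_field=True)
        r_beta = set(recipient.alleles_at("DQB1"))
        r_alpha = set(recipient.alleles_at("DQA1"))
        per["DQ"] = sum(
            1 for b, a in donor_dq_units(donor)
            if b not in r_beta or a not in r_alpha
        )
        class_i = per["A"] + per["B"] + per["C"]
        class_ii = per["DRB1"] + per["DQ"] + per["DPB1"]
    else:
        raise ValueError(f"unknown mismatch mode {mode!r}; expected LR3 or HR6")
    return MismatchCounts(mode, per, class_i, class_ii, class_i + class_ii)


# ---------------------------------------------------------------------------
# typing table I/O

TYPING_COLUMNS = ["subject_id", "locus", "allele1", "allele2", "provenance"]


def read_typing_table(path) -> dict[str, Genotype]:
    """Read a per-locus typing TSV into genotypes keyed by subject id.

    Columns: subject_id, locus, allele1, allele2, provenance; a blank
    allele2 encodes homozygosity, a blank allele1 with provenance
    ``unavailable`` encodes an untyped locus.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TYPING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"typing table {path} lacks columns {missing}")
    genotypes: dict[str, Genotype] = {}
    for row in df.itertuples(index=False):
        g = genotypes.setdefault(str(row.subject_id), Genotype(str(row.subject_id)))
        alleles = [parse_allele(s) for s in (row.allele1, row.allele2) if s]
        g.set_locus(row.locus, LocusTyping(_dedupe(alleles), row.provenance))
    return genotypes


def write_typing_table(genotypes: Iterable[Genotype], path) -> None:
    rows = []
    for g in genotypes:
        for locus in g.loci:
            alleles = g.alleles_at(locus)
            rows.append({
                "subject_id": g.subject_id,
                "locus": locus,
                "allele1": str(alleles[0]) if alleles else "",
                "allele2": str(alleles[1]) if len(alleles) > 1 else "",
                "provenance": g.provenance(locus),
            })
    pd.DataFrame(rows, columns=TYPING_COLUMNS).to_csv(path, sep="\t", index=False)
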