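"""HLAMatchmaker-style eplet set algebra.

An eplet is a small patch of polymorphic surface residues that an antibody
can engage.  A registry maps each two-field allele to its eplet set and
flags, globally per eplet name, whether antibody reactivity against it has
been experimentally verified (AbV).  The donor/recipient eplet mismatch
(EpMM) of a scope is the union of donor-allele eplets minus the union of
recipient-allele eplets; the non-shared eplets of a presumed antibody
target relative to the actual donor allele explain why an antigen-level
DSA call can dissolve at allele-level resolution.

Registry contents are versioned external data supplied by the user as a
CSV (columns ``allele, eplet, abv``); nothing here depends on a specific
HLAMatchmaker release.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import RegistryLookupError, ResolutionError
from .hla import Allele, Genotype, parse_allele

#: locus sets entering each named scope
SCOPE_LOCI = {
    "class_I_AB": ("A", "B"),
    "class_I": ("A", "B", "C"),
    "class_II_DRDQ": ("DRB1", "DQA1", "DQB1"),
    "class_II": ("DRB1", "DQA1", "DQB1", "DPA1", "DPB1"),
    "DQ": ("DQA1", "DQB1"),
    "DRB1": ("DRB1",),
}


class EpletRegistry:
    """allele -> eplet-name set, with global antibody-verified flags."""

    def __init__(self, allele_eplets: Mapping[Allele, Iterable[str]],
                 verified: Iterable[str] = ()) -> None:
        self._map: dict[Allele, frozenset[str]] = {}
        for allele, eplets in allele_eplets.items():
            if not allele.is_two_field:
                raise ResolutionError(
                    f"registry alleles must be two-field, got {allele}"
                )
            self._map[allele] = frozenset(eplets)
        self.verified = frozenset(verified)

    @classmethod
    def from_csv(cls, path) -> "EpletRegistry":
        df = pd.read_csv(path, dtype={"allele": str, "eplet": str, "abv": int})
        mapping: dict[Allele, set[str]] = {}
        verified: set[str] = set()
        for r in df.itertuples(index=False):
            a = parse_allele(r.allele)
            mapping.setdefault(a, set()).add(r.eplet)
            if int(r.abv):
                verified.add(r.eplet)
        return cls(mapping, verified)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"allele": str(a), "eplet": e, "abv": int(e in self.verified)}
            for a in sorted(self._map) for e in sorted(self._map[a])
        ]
        return pd.DataFrame(rows, columns=["allele", "eplet", "abv"])

    def __contains__(self, allele: Allele) -> bool:
        return allele in self._map

    def eplets(self, allele: Allele) -> frozenset[str]:
        try:
            return self._map[allele]
        except KeyError:
            raise RegistryLookupError(
                f"allele {allele} not in registry"
            ) from None

    def union(self, alleles: Iterable[Allele]) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        missing = []
        for a in alleles:
            if a in self._map:
                out |= self._map[a]
            else:
                missing.append(str(a))
        if missing:
            raise RegistryLookupError(
                f"alleles not in registry: {', '.join(missing)}"
            )
        return out

    @property
    def alleles(self) -> tuple[Allele, ...]:
        return tuple(sorted(self._map))


def eplet_set(allele: Allele, registry: EpletRegistry) -> frozenset[str]:
    """The registry's eplet set for one allele (error when unregistered)."""
    return registry.eplets(allele)


@dataclass(frozen=True)
class EpMMResult:
    scope: str
    eplets: frozenset[str]
    verified_eplets: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.eplets)

    @property
    def verified_count(self) -> int:
        return len(self.verified_eplets)


def mismatched_eplets(donor_alleles: Sequence[Allele],
                      recipient_alleles: Sequence[Allele],
                      registry: EpletRegistry,
                      scope: str = "custom") -> EpMMResult:
    """Donor-minus-recipient eplet set difference over explicit allele lists."""
    diff = registry.union(donor_alleles) - registry.union(recipient_alleles)
    return EpMMResult(scope, diff, diff & registry.verified)


def nonshared_eplets(presumed_target: Allele, actual_donor: Allele,
                     recipient_alleles: Sequence[Allele],
                     registry: EpletRegistry) -> list[tuple[str, bool]]:
    """Eplets unique to the antibody-reactive allele.

    Eplets carried by the presumed target but absent from both the actual
    donor allele and every recipient allele, annotated with the AbV flag.
    An empty list means the two alleles expose no distinguishing eplet and
    the antigen-level call cannot be explained by eplet content.
    """
    diff = (registry.eplets(presumed_target)
            - registry.eplets(actual_donor)
            - registry.union(recipient_alleles))
    return [(e, e in registry.verified) for e in sorted(diff)]


def epmm_profile(recipient: Genotype, donor: Genotype,
                 registry: EpletRegistry,
                 scopes: Sequence[str] = ("class_I_AB", "class_I",
                                          "class_II_DRDQ", "class_II",
                                          "DQ", "DRB1"),
                 interlocus_dedup: bool = True) -> dict[str, EpMMResult]:
    """Per-scope donor/recipient EpMM for one pair.

    The recipient union is taken over all recipient alleles of the scope
    (genotype level).  With ``interlocus_dedup`` (the HLAMatchmaker
    convention) eplet names shared between loci of a scope count once;
    switching it off sums per-locus differences instead.
    """
    out: dict[str, EpMMResult] = {}
    for scope in scopes:
        loci = SCOPE_LOCI[scope]
        loci = [l for l in loci if donor.available(l) or recipient.available(l)]
        if interlocus_dedup:
            d = [a for l in loci for a in donor.alleles_at(l)]
            r = [a for l in loci for a in recipient.alleles_at(l)]
            out[scope] = mismatched_eplets(d, r, registry, scope)
        else:
            eplets: frozenset[str] = frozenset()
            for l in loci:
                res = mismatched_eplets(list(donor.alleles_at(l)),
                                        list(recipient.alleles_at(l)),
                                        registry, scope)
                eplets |= frozenset(f"{l}:{e}" for e in res.eplets)
            verified = frozenset(
                e for e in eplets if e.split(":", 1)[1] in registry.verified
            )
            out[scope] = EpMMResult(scope, eplets, verified)
    return out
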