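"""Haplotype-frequency imputation of untyped HLA loci.

Clinical labs that only hold one-field A/B/DRB1 donor typing estimate the
donor's HLA-C and -DQ alleles from population haplotype frequency tables
when an antibody against those loci is found.  This module re-implements
that estimation generically over a user-supplied frequency table: all
unordered haplotype pairs compatible with the observed genotype are
enumerated, weighted by the product of their population frequencies under
Hardy-Weinberg random pairing, and the maximum-weight pair supplies a
point estimate for the untyped loci.

A one-field observed allele matches any two-field table allele sharing its
allele group; a two-field observed allele must match exactly.  Ties between
equal-weight pairs break lexicographically on the serialized haplotypes so
results are deterministic, and the normalized probability of the chosen
pair is reported so callers can flag low-confidence expansions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ImputationError
from .hla import (
    IMPUTED,
    Allele,
    Genotype,
    LocusTyping,
    antigen_match,
    parse_allele,
)

FREQ_TOL = 1e-6


@dataclass(frozen=True)
class Haplotype:
    """A multi-locus haplotype; ``alleles`` aligns with the table's loci."""

    alleles: tuple[Allele, ...]

    def allele_at(self, loci: Sequence[str], locus: str) -> Allele:
        return self.alleles[loci.index(locus)]

    def __str__(self) -> str:
        return "~".join(str(a) for a in self.alleles)


class HaplotypeTable:
    """Population haplotypes with frequencies over a fixed locus set."""

    def __init__(self, loci: Sequence[str],
                 rows: Iterable[tuple[Haplotype, float]],
                 population: str = "") -> None:
        self.loci = tuple(loci)
        self.rows = [(h, float(f)) for h, f in rows]
        self.population = population
        for h, f in self.rows:
            if len(h.alleles) != len(self.loci):
                raise ValueError(f"haplotype {h} does not cover loci {self.loci}")
            for a, locus in zip(h.alleles, self.loci):
                if a.locus != locus:
                    raise ValueError(f"allele {a} under locus column {locus}")
            if f <= 0:
                raise ValueError(f"non-positive haplotype frequency {f} for {h}")
        total = sum(f for _, f in self.rows)
        if total > 1 + FREQ_TOL:
            raise ValueError(f"haplotype frequencies sum to {total} > 1")

    @classmethod
    def from_csv(cls, path, population: str | None = None) -> "HaplotypeTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "freq" not in df.columns:
            raise ValueError(f"haplotype table {path} lacks a 'freq' column")
        loci = [c for c in df.columns if c not in ("freq", "population")]
        if population is not None and "population" in df.columns:
            df = df[df["population"] == population]
        rows = [
            (Haplotype(tuple(parse_allele(getattr(r, l)) for l in loci)),
             float(r.freq))
            for r in df.itertuples(index=False)
        ]
        pop = population or (df["population"].iloc[0]
                             if "population" in df.columns and len(df) else "")
        return cls(loci, rows, population=pop)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for h, f in self.rows:
            rec = {l: str(a) for l, a in zip(self.loci, h.alleles)}
            rec["freq"] = f
            if self.population:
                rec["population"] = self.population
            records.append(rec)
        return pd.DataFrame(records)


@dataclass
class ImputationResult:
    genotype: Genotype
    probability: float
    #: (haplotype pair, normalized probability), best first
    ranked_pairs: list


def _matches_observed(table_allele: Allele, observed: Allele) -> bool:
    if observed.is_two_field:
        return table_allele == observed
    return antigen_match(table_allele, observed)


def _pair_compatible(h1: Haplotype, h2: Haplotype, loci: Sequence[str],
                     observed: Genotype) -> bool:
    for locus in loci:
        if not observed.available(locus):
            continue
        obs = observed.alleles_at(locus)
        a1 = h1.allele_at(loci, locus)
        a2 = h2.allele_at(loci, locus)
        if len(obs) == 1:  # homozygous observation: both chromosomes match it
            if not (_matches_observed(a1, obs[0]) and _matches_observed(a2, obs[0])):
                return False
        else:
            x, y = obs
            if not ((_matches_observed(a1, x) and _matches_observed(a2, y))
                    or (_matches_observed(a1, y) and _matches_observed(a2, x))):
                return False
    return True


def enumerate_compatible_pairs(observed: Genotype, table: HaplotypeTable
                               ) -> list[tuple[tuple[Haplotype, Haplotype], float]]:
    """All unordered haplotype pairs reproducing the observed genotype.

    The weight of a pair is ``f(h1)*f(h2)``, doubled for heterozygous pairs
    (two orderings under random union of gametes).  Returns an empty list
    when nothing in the table is compatible.
    """
    unknown = [l for l in observed.loci
               if observed.available(l) and l not in table.loci]
    if unknown:
        raise ValueError(f"observed loci {unknown} not covered by the table")
    out = []
    for (h1, f1), (h2, f2) in itertools.combinations_with_replacement(table.rows, 2):
        if _pair_compatible(h1, h2, table.loci, observed):
            w = f1 * f2 * (2.0 if h1 != h2 else 1.0)
            out.append(((h1, h2), w))
    return out


def _pair_key(pair: tuple[Haplotype, Haplotype]) -> tuple[str, str]:
    return tuple(sorted((str(pair[0]), str(pair[1]))))


def impute_loci(observed: Genotype, table: HaplotypeTable,
                target_loci: Sequence[str]) -> ImputationResult:
    """Fill untyped target loci from the maximum-probability haplotype pair.

    Raises
    ------
    ImputationError
        If no haplotype pair in the table is compatible with the observed
        genotype (never silently returns a partial result).
    """
    for locus in target_loci:
        if locus not in table.loci:
            raise ValueError(f"target locus {locus} not in table loci {table.loci}")
    pairs = enumerate_compatible_pairs(observed, table)
    if not pairs:
        raise ImputationError(
            f"genotype of {observed.subject_id} is inconsistent with the "
            f"haplotype panel ({table.population or 'unnamed population'})"
        )
    total = sum(w for _, w in pairs)
    ranked = sorted(pairs, key=lambda pw: (-pw[1], _pair_key(pw[0])))
    best_pair, best_w = ranked[0]
    expanded = Genotype(observed.subject_id)
    for locus in observed.loci:
        expanded.set_locus(locus, LocusTyping(observed.alleles_at(locus),
                                              observed.provenance(locus)))
    for locus in target_loci:
        alleles = []
        for h in best_pair:
            a = h.allele_at(table.loci, locus)
            if a not in alleles:
                alleles.append(a)
        expanded.set_locus(locus, LocusTyping(tuple(alleles), IMPUTED))
    return ImputationResult(
        genotype=expanded,
        probability=best_w / total,
        ranked_pairs=[(p, w / total) for p, w in ranked],
    )


def expand_lr_genotype(observed: Genotype, table: HaplotypeTable,
                       target_loci: Sequence[str]) -> ImputationResult:
    """Impute target loci and refine observed one-field loci to two-field.

    Eplet mismatch computation needs two-field alleles everywhere, so the
    best pair also supplies protein-level refinements of the loci that were
    observed at one field (provenance becomes ``imputed`` for those).
    """
    result = impute_loci(observed, table, target_loci)
    best_pair, _ = result.ranked_pairs[0]
    g = result.genotype
    for locus in observed.loci:
        if not observed.available(locus) or locus in target_loci:
            continue
        if all(a.is_two_field for a in observed.alleles_at(locus)):
            continue
        alleles = []
        for h in best_pair:
            a = h.allele_at(table.loci, locus)
            if a not in alleles:
                alleles.append(a)
        g.set_locus(locus, LocusTyping(tuple(alleles), IMPUTED))
    return result
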