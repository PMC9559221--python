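import numpy as np
import pytest

from hladsa.fixtures import load_fixture, load_registry
from hladsa.hla import TYPED, Allele, Genotype, LocusTyping, parse_allele
from hladsa.imputation import Haplotype, HaplotypeTable


@pytest.fixture(scope="session")
def table3():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_registry():
    return load_registry()


def make_genotype(subject_id, **loci):
    """loci: locus -> allele string or (strings, provenance)."""
    g = Genotype(subject_id)
    for locus, val in loci.items():
        if isinstance(val, tuple) and len(val) == 2 and isinstance(val[1], str) \
                and val[1] in ("typed", "imputed", "unavailable"):
            alleles, prov = val
        else:
            alleles, prov = val, TYPED
        if isinstance(alleles, str):
            alleles = [alleles]
        parsed = tuple(dict.fromkeys(parse_allele(a) for a in alleles))
        g.set_locus(locus, LocusTyping(parsed, prov))
    return g


def toy_haplotype_table(rows, loci=("A", "B", "C")):
    """rows: list of (allele-string tuple, freq)."""
    return HaplotypeTable(
        loci,
        [(Haplotype(tuple(parse_allele(s) for s in alleles)), f)
         for alleles, f in rows],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_two_field(rng, locus, n_groups=5, n_proteins=4) -> Allele:
    return Allele(locus, int(rng.integers(1, n_groups + 1)),
                  int(rng.integers(1, n_proteins + 1)))
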