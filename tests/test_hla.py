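"""HLA nomenclature, matching predicates, and antigen mismatch counting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genotype, random_two_field
from hladsa.errors import AlleleParseError, MissingLocusError, ResolutionError
from hladsa.hla import (
    LOCI,
    Allele,
    LocusTyping,
    allele_match,
    antigen_match,
    count_antigen_mm,
    parse_allele,
    read_typing_table,
    reduce_to_one_field,
    write_typing_table,
)


class TestParsing:
    @pytest.mark.parametrize("text,locus,f1,f2", [
        ("A*11:01", "A", 11, 1),
        ("DRB1*11", "DRB1", 11, None),
        ("DQA1*05:05", "DQA1", 5, 5),
        ("DPB1*104:01", "DPB1", 104, 1),
        (" B*44:03 ", "B", 44, 3),
    ])
    def test_parse(self, text, locus, f1, f2):
        a = parse_allele(text)
        assert (a.locus, a.field1, a.field2) == (locus, f1, f2)
        assert a.is_two_field == (f2 is not None)

    @pytest.mark.parametrize("bad", ["A11:01", "ZZ*01:01", "A*", "A*01:",
                                     "A*01:01:01N", ""])
    def test_parse_errors_name_the_token(self, bad):
        with pytest.raises(AlleleParseError):
            parse_allele(bad)

    @given(st.sampled_from(LOCI), st.integers(1, 99),
           st.one_of(st.none(), st.integers(1, 199)))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_serialize_parse_roundtrip(self, locus, f1, f2):
        a = Allele(locus, f1, f2)
        assert parse_allele(str(a)) == a


class TestResolution:
    def test_reduce_drops_protein_field(self):
        assert str(reduce_to_one_field(parse_allele("A*11:02"))) == "A*11"
        assert str(reduce_to_one_field(parse_allele("B*44:03"))) == "B*44"

    def test_reduce_is_idempotent(self):
        a = parse_allele("A*11")
        assert reduce_to_one_field(a) == a

    def test_antigen_match_is_first_field_equality(self):
        assert antigen_match(parse_allele("A*11:01"), parse_allele("A*11"))
        assert antigen_match(parse_allele("B*15:12"), parse_allele("B*15"))
        assert not antigen_match(parse_allele("A*11:01"), parse_allele("B*11"))

    def test_allele_match_is_exact_two_field(self):
        assert not allele_match(parse_allele("A*11:01"), parse_allele("A*11:02"))
        assert allele_match(parse_allele("C*05:01"), parse_allele("C*05:01"))
        with pytest.raises(ResolutionError):
            allele_match(parse_allele("A*11"), parse_allele("A*11:01"))


def _brute_force_mm(recipient, donor, mode):
    """Independent oracle: explicit set difference per locus."""
    if mode == "LR3":
        per = {}
        for locus in ("A", "B", "DRB1"):
            d = {a.field1 for a in donor.alleles_at(locus)}
            r = {a.field1 for a in recipient.alleles_at(locus)}
            per[locus] = len(d - r)
        return per, per["A"] + per["B"], per["DRB1"]
    per = {}
    for locus in ("A", "B", "C", "DRB1", "DPB1"):
        per[locus] = len(set(donor.alleles_at(locus))
                         - set(recipient.alleles_at(locus)))
    betas = donor.alleles_at("DQB1")
    alphas = donor.alleles_at("DQA1")
    units = set()
    for i, b in enumerate(betas):
        units.add((b, alphas[min(i, len(alphas) - 1)]))
    per["DQ"] = sum(1 for b, a in units
                    if b not in recipient.alleles_at("DQB1")
                    or a not in recipient.alleles_at("DQA1"))
    ci = per["A"] + per["B"] + per["C"]
    cii = per["DRB1"] + per["DQ"] + per["DPB1"]
    return per, ci, cii


def _random_hr_genotype(rng, sid):
    loci = {}
    for locus in ("A", "B", "C", "DRB1", "DQB1", "DQA1", "DPB1"):
        alleles = tuple(dict.fromkeys(
            random_two_field(rng, locus) for _ in range(2)))
        loci[locus] = (alleles, "typed")
    from hladsa.hla import Genotype
    g = Genotype(sid)
    for locus, (alleles, prov) in loci.items():
        g.set_locus(locus, LocusTyping(alleles, prov))
    return g


class TestMismatchCounting:
    def test_identical_pair_counts_zero(self):
        g = make_genotype("x", A=["A*01:01", "A*02:01"], B=["B*07:02", "B*08:01"],
                          C=["C*07:01"], DRB1=["DRB1*03:01"],
                          DQB1=["DQB1*02:01"], DQA1=["DQA1*05:01"],
                          DPB1=["DPB1*04:01"])
        for mode in ("LR3", "HR6"):
            counts = count_antigen_mm(g, g, mode)
            assert counts.total == counts.class_i == counts.class_ii == 0

    def test_fully_disjoint_pair_reaches_scale_maximum(self):
        r = make_genotype("r", A=["A*01:01", "A*02:01"], B=["B*07:02", "B*08:01"],
                          C=["C*01:02", "C*02:02"], DRB1=["DRB1*01:01", "DRB1*03:01"],
                          DQB1=["DQB1*02:01", "DQB1*03:01"],
                          DQA1=["DQA1*01:01", "DQA1*02:01"],
                          DPB1=["DPB1*01:01", "DPB1*02:01"])
        d = make_genotype("d", A=["A*03:01", "A*11:01"], B=["B*15:01", "B*18:01"],
                          C=["C*04:01", "C*05:01"], DRB1=["DRB1*04:01", "DRB1*07:01"],
                          DQB1=["DQB1*05:01", "DQB1*06:02"],
                          DQA1=["DQA1*03:01", "DQA1*05:01"],
                          DPB1=["DPB1*03:01", "DPB1*04:01"])
        hr = count_antigen_mm(r, d, "HR6")
        assert (hr.class_i, hr.class_ii, hr.total) == (6, 6, 12)
        lr = count_antigen_mm(r, d, "LR3")
        assert lr.total == 6

    def test_homozygous_donor_contributes_once(self):
        r = make_genotype("r", A=["A*01:01", "A*02:01"], B=["B*07:02"],
                          DRB1=["DRB1*03:01"])
        d = make_genotype("d", A=["A*03:01"], B=["B*07:02"], DRB1=["DRB1*03:01"])
        assert count_antigen_mm(r, d, "LR3").total == 1

    def test_random_pairs_match_brute_force_oracle(self, rng):
        for _ in range(20):
            r = _random_hr_genotype(rng, "r")
            d = _random_hr_genotype(rng, "d")
            got = count_antigen_mm(r, d, "HR6")
            per, ci, cii = _brute_force_mm(r, d, "HR6")
            assert got.per_locus == per
            assert (got.class_i, got.class_ii) == (ci, cii)

    def test_adding_recipient_allele_never_increases_counts(self, rng):
        for _ in range(10):
            r = _random_hr_genotype(rng, "r")
            d = _random_hr_genotype(rng, "d")
            base = count_antigen_mm(r, d, "HR6")
            locus = ("A", "B", "C", "DRB1", "DPB1")[int(rng.integers(5))]
            extra = random_two_field(rng, locus)
            alleles = r.alleles_at(locus)
            if len(alleles) != 1 or extra in alleles:
                continue
            r.set_locus(locus, LocusTyping(alleles + (extra,), "typed"))
            grown = count_antigen_mm(r, d, "HR6")
            assert grown.total <= base.total
            assert all(grown.per_locus[l] <= base.per_locus[l]
                       for l in base.per_locus)

    def test_lr_count_bounded_by_hr_count_on_refining_pairs(self, rng):
        for _ in range(10):
            r = _random_hr_genotype(rng, "r")
            d = _random_hr_genotype(rng, "d")
            lr = count_antigen_mm(r, d, "LR3")
            hr = count_antigen_mm(r, d, "HR6")
            assert lr.total <= hr.total

    def test_missing_locus_raises_naming_the_locus(self):
        r = make_genotype("r", A=["A*01:01"], B=["B*07:02"])
        d = make_genotype("d", A=["A*01:01"], B=["B*07:02"], DRB1=["DRB1*03:01"])
        with pytest.raises(MissingLocusError, match="DRB1"):
            count_antigen_mm(r, d, "LR3")


def test_typing_table_roundtrip(tmp_path):
    g = make_genotype("s1", A=["A*01:01", "A*02:01"], B=["B*07:02"],
                      C=(["C*07:01"], "imputed"), DPB1=([], "unavailable"))
    path = tmp_path / "typing.tsv"
    write_typing_table([g], path)
    back = read_typing_table(path)["s1"]
    assert back == g
    assert back.provenance("C") == "imputed"
    assert back.provenance("DPB1") == "unavailable"
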