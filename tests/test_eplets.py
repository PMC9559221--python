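"""Eplet set algebra: registry lookups, EpMM counts, non-shared eplets."""

import pytest

from conftest import make_genotype
from hladsa.eplets import (
    EpletRegistry,
    epmm_profile,
    eplet_set,
    mismatched_eplets,
    nonshared_eplets,
)
from hladsa.errors import RegistryLookupError
from hladsa.hla import parse_allele


def reg(mapping, verified=()):
    return EpletRegistry({parse_allele(a): set(e) for a, e in mapping.items()},
                         verified)


class TestRegistry:
    def test_lookup_returns_the_registered_set(self):
        r = reg({"A*01:01": {"e1", "e2"}})
        assert eplet_set(parse_allele("A*01:01"), r) == {"e1", "e2"}

    def test_unregistered_allele_is_an_error(self):
        r = reg({"A*01:01": {"e1"}})
        with pytest.raises(RegistryLookupError, match="B\\*99:99"):
            eplet_set(parse_allele("B*99:99"), r)

    def test_fixture_registry_carries_the_19k_eplet(self, fixture_registry):
        assert "19K" in eplet_set(parse_allele("A*11:01"), fixture_registry)

    def test_one_field_allele_rejected(self):
        with pytest.raises(Exception):
            reg({"A*01": {"e1"}})

    def test_csv_roundtrip(self, tmp_path, fixture_registry):
        path = tmp_path / "reg.csv"
        fixture_registry.to_frame().to_csv(path, index=False)
        back = EpletRegistry.from_csv(path)
        for a in fixture_registry.alleles:
            assert back.eplets(a) == fixture_registry.eplets(a)
        assert back.verified == fixture_registry.verified


class TestMismatchedEplets:
    def test_identity_gives_empty_set(self):
        r = reg({"A*01:01": {"e1", "e2"}})
        a = [parse_allele("A*01:01")]
        assert mismatched_eplets(a, a, r).count == 0

    def test_forced_set_algebra(self):
        r = reg({"A*01:01": {"e1", "e2", "e3"}, "A*02:01": {"e2"}},
                verified={"e1"})
        res = mismatched_eplets([parse_allele("A*01:01")],
                                [parse_allele("A*02:01")], r)
        assert res.eplets == {"e1", "e3"}
        assert res.count == 2
        assert res.verified_count == 1

    def test_random_registries_match_brute_force_oracle(self, rng):
        universe = [f"e{i}" for i in range(30)]
        for _ in range(50):
            alleles = [f"A*{g:02d}:{p:02d}" for g in range(1, 4)
                       for p in range(1, 4)]
            mapping = {a: set(rng.choice(universe,
                                         size=int(rng.integers(2, 9)),
                                         replace=False))
                       for a in alleles}
            verified = set(rng.choice(universe, size=6, replace=False))
            r = reg(mapping, verified)
            donor = list(rng.choice(alleles, size=2, replace=False))
            recip = list(rng.choice(alleles, size=2, replace=False))
            got = mismatched_eplets([parse_allele(a) for a in donor],
                                    [parse_allele(a) for a in recip], r)
            # oracle: plain python set union/difference over the raw mapping
            want = (mapping[donor[0]] | mapping[donor[1]]) \
                - (mapping[recip[0]] | mapping[recip[1]])
            assert got.eplets == want
            assert got.verified_eplets == want & verified

    def test_adding_recipient_allele_never_increases_count(self, rng):
        r = reg({"A*01:01": {"e1", "e2", "e3"}, "A*02:01": {"e2", "e4"},
                 "A*03:01": {"e3"}})
        donor = [parse_allele("A*01:01"), parse_allele("A*02:01")]
        base = mismatched_eplets(donor, [parse_allele("A*02:01")], r)
        grown = mismatched_eplets(donor, [parse_allele("A*02:01"),
                                          parse_allele("A*03:01")], r)
        assert grown.count <= base.count


class TestNonShared:
    @pytest.mark.parametrize("presumed,actual,expected", [
        ("DRB1*11:03", "DRB1*11:04", [("71E", False)]),
        ("A*11:01", "A*11:02", [("19K", False)]),
        ("A*02:05", "A*02:01", [("43R", False)]),
        ("B*15:12", "B*15:17", [("156WA", False)]),
        ("B*35:08", "B*35:01", []),
        ("A*29:01", "A*29:02", []),
    ])
    def test_worked_cohort_annotations(self, fixture_registry, presumed,
                                       actual, expected):
        got = nonshared_eplets(parse_allele(presumed), parse_allele(actual),
                               [], fixture_registry)
        assert got == expected

    def test_alpha_chain_annotations(self, fixture_registry):
        got = nonshared_eplets(parse_allele("DQA1*04:01"),
                               parse_allele("DQA1*03:02"), [],
                               fixture_registry)
        assert got == [("40GR", True), ("69T", False), ("76L", False)]
        got = nonshared_eplets(parse_allele("DQA1*02:01"),
                               parse_allele("DQA1*05:01"), [],
                               fixture_registry)
        assert got == [("47KHL", True)]

    def test_identical_alleles_share_everything(self, fixture_registry):
        a = parse_allele("A*11:01")
        assert nonshared_eplets(a, a, [], fixture_registry) == []

    def test_recipient_eplets_are_subtracted(self):
        r = reg({"A*01:01": {"e1", "e2"}, "A*02:01": {"e2"},
                 "B*07:02": {"e1"}})
        got = nonshared_eplets(parse_allele("A*01:01"), parse_allele("A*02:01"),
                               [parse_allele("B*07:02")], r)
        assert got == []


class TestProfiles:
    def _pair_registry(self):
        return reg({
            "A*01:01": {"a1", "x"}, "A*02:01": {"a2", "x"},
            "B*07:02": {"b1"}, "B*08:01": {"b2"},
            "DRB1*03:01": {"d1", "s"}, "DRB1*04:01": {"d2", "s"},
            "DQB1*02:01": {"q1", "s"}, "DQB1*03:01": {"q2"},
            "DQA1*05:01": {"qa1"}, "DQA1*03:01": {"qa2"},
        }, verified={"a2", "q1"})

    def test_identical_pair_all_scopes_zero(self):
        r = self._pair_registry()
        g = make_genotype("x", A=["A*01:01"], B=["B*07:02"],
                          DRB1=["DRB1*03:01"], DQB1=["DQB1*02:01"],
                          DQA1=["DQA1*05:01"])
        prof = epmm_profile(g, g, r, scopes=("class_I_AB", "class_II_DRDQ",
                                             "DQ", "DRB1"))
        assert all(res.count == 0 for res in prof.values())

    def test_exact_imputation_equals_direct_hr(self):
        r = self._pair_registry()
        recip = make_genotype("r", A=["A*01:01"], B=["B*07:02"],
                              DRB1=["DRB1*03:01"], DQB1=["DQB1*02:01"],
                              DQA1=["DQA1*05:01"])
        donor_hr = make_genotype("d", A=["A*02:01"], B=["B*08:01"],
                                 DRB1=["DRB1*04:01"], DQB1=["DQB1*03:01"],
                                 DQA1=["DQA1*03:01"])
        donor_imp = make_genotype("d", A=["A*02:01"], B=["B*08:01"],
                                  DRB1=["DRB1*04:01"],
                                  DQB1=(["DQB1*03:01"], "imputed"),
                                  DQA1=(["DQA1*03:01"], "imputed"))
        scopes = ("class_I_AB", "class_II_DRDQ", "DQ", "DRB1")
        hr = epmm_profile(recip, donor_hr, r, scopes=scopes)
        lr = epmm_profile(recip, donor_imp, r, scopes=scopes)
        for scope in scopes:
            assert hr[scope].eplets == lr[scope].eplets

    def test_interlocus_dedup_only_matters_for_shared_names(self):
        r = self._pair_registry()
        recip = make_genotype("r", DRB1=["DRB1*03:01"], DQB1=["DQB1*03:01"],
                              DQA1=["DQA1*03:01"])
        donor = make_genotype("d", DRB1=["DRB1*04:01"], DQB1=["DQB1*02:01"],
                              DQA1=["DQA1*05:01"])
        dedup = epmm_profile(recip, donor, r, scopes=("class_II_DRDQ",))
        plain = epmm_profile(recip, donor, r, scopes=("class_II_DRDQ",),
                             interlocus_dedup=False)
        # 's' is carried by both DRB1*04:01 and DQB1*02:01 donor alleles but
        # the recipient's DRB1 also carries it, so dedup keeps it out once
        assert dedup["class_II_DRDQ"].count <= plain["class_II_DRDQ"].count

    def test_class_ii_union_bounded_by_per_locus_sum(self):
        r = self._pair_registry()
        recip = make_genotype("r", DRB1=["DRB1*03:01"], DQB1=["DQB1*03:01"],
                              DQA1=["DQA1*03:01"])
        donor = make_genotype("d", DRB1=["DRB1*04:01"], DQB1=["DQB1*02:01"],
                              DQA1=["DQA1*05:01"])
        whole = epmm_profile(recip, donor, r, scopes=("class_II_DRDQ",))
        drb = epmm_profile(recip, donor, r, scopes=("DRB1",))
        dq = epmm_profile(recip, donor, r, scopes=("DQ",))
        assert whole["class_II_DRDQ"].count <= (drb["DRB1"].count
                                                + dq["DQ"].count)

    def test_lr_hr_agreement_degrades_when_dq_scope_added(self):
        """Imputation noise at DQ lowers the LR/HR profile correlation once
        DQ enters the class II scope."""
        from scipy.stats import spearmanr

        from hladsa.hla import Genotype, LocusTyping
        from hladsa.simulate import SimulationConfig, generate_cohort

        cohort = generate_cohort(SimulationConfig(), 21)
        reg_syn = cohort.registry
        lr_drb, hr_drb, lr_drdq, hr_drdq = [], [], [], []
        for pid, donor in cohort.donors_hr.items():
            rid = "R" + pid[1:]
            recip = cohort.recipients[rid]
            lr_view = cohort.donors_lr[pid]
            # LR-expanded donor: protein-level DRB1 plus estimated DQ
            expanded = Genotype(pid)
            expanded.set_locus("DRB1", LocusTyping(
                donor.alleles_at("DRB1"), "typed"))
            for locus in ("DQB1", "DQA1"):
                expanded.set_locus(locus, LocusTyping(
                    lr_view.alleles_at(locus), "imputed"))
            scopes = ("class_II_DRDQ", "DRB1")
            hr_prof = epmm_profile(recip, donor, reg_syn, scopes=scopes)
            lr_prof = epmm_profile(recip, expanded, reg_syn, scopes=scopes)
            lr_drb.append(lr_prof["DRB1"].count)
            hr_drb.append(hr_prof["DRB1"].count)
            lr_drdq.append(lr_prof["class_II_DRDQ"].count)
            hr_drdq.append(hr_prof["class_II_DRDQ"].count)
        r_drb = spearmanr(lr_drb, hr_drb).statistic
        r_drdq = spearmanr(lr_drdq, hr_drdq).statistic
        assert r_drb == pytest.approx(1.0)
        assert r_drdq < r_drb
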