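import itertools

import pytest

from dnmpipe.dnm_calling import (
    CandidateDNM,
    classify_substitution,
    concordance_confirm,
    find_candidates,
    mendelian_consistency,
    read_candidates_tsv,
    summarize_validation,
    write_candidates_tsv,
)
from dnmpipe.pedigree_data import IntervalSet, Pedigree
from helpers import call, permissive_thresholds, site


@pytest.fixture
def ped():
    return Pedigree("m", "f", ("o1", "o2"))


def violation_site(pos=100, off_ad=(14, 12), offspring="o1"):
    calls = {
        "m": call(("A", "A"), (15, 0)),
        "f": call(("A", "A"), (13, 0)),
        "o1": call(("A", "A"), (12, 0)),
        "o2": call(("A", "A"), (11, 0)),
    }
    calls[offspring] = call(("A", "G"), off_ad)
    return site(pos, calls)


class TestClassifySubstitution:
    def test_partition_into_4_transitions_8_transversions(self):
        pairs = [(a, b) for a, b in itertools.permutations("ACGT", 2)]
        classes = [classify_substitution(a, b) for a, b in pairs]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8
        assert classify_substitution("C", "T") == "transition"
        assert classify_substitution("A", "G") == "transition"
        assert classify_substitution("A", "C") == "transversion"

    def test_identical_bases_fatal(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestFindCandidates:
    def test_mendelian_violation_detected(self, ped):
        thr = permissive_thresholds(ped.samples)
        cands = find_candidates([violation_site()], ped, thr, IntervalSet())
        assert len(cands) == 1
        c = cands[0]
        assert (c.offspring_id, c.parental_allele, c.mutant_allele) == ("o1", "A", "G")
        assert c.offspring_allele_balance == pytest.approx(12 / 26)
        assert c.substitution_class == "transition"

    def test_low_mutant_support_rejected(self, ped):
        thr = permissive_thresholds(ped.samples)
        cands = find_candidates([violation_site(off_ad=(16, 4))], ped, thr, IntervalSet())
        assert cands == []  # AB 0.2 < 0.25

    def test_het_parent_site_not_screened(self, ped):
        s = violation_site()
        s.calls["f"] = call(("A", "G"), (7, 7))
        thr = permissive_thresholds(ped.samples)
        assert find_candidates([s], ped, thr, IntervalSet()) == []

    def test_opposite_hom_parents_not_screened(self, ped):
        s = violation_site()
        s.calls["f"] = call(("G", "G"), (0, 12))
        thr = permissive_thresholds(ped.samples)
        assert find_candidates([s], ped, thr, IntervalSet()) == []

    def test_noisy_parent_excluded(self, ped):
        s = violation_site()
        s.calls["m"] = call(("A", "A"), (13, 2))  # minor AB 0.133 >= 0.1
        thr = permissive_thresholds(ped.samples)
        assert find_candidates([s], ped, thr, IntervalSet()) == []

    def test_uncallable_site_skipped(self, ped):
        thr = permissive_thresholds(ped.samples, depth=(100, 200))
        assert find_candidates([violation_site()], ped, thr, IntervalSet()) == []

    def test_back_mutation_toward_reference(self, ped):
        s = site(100, {
            "m": call(("G", "G"), (0, 15)),
            "f": call(("G", "G"), (0, 13)),
            "o1": call(("A", "G"), (6, 7)),
            "o2": call(("G", "G"), (0, 11)),
        })
        thr = permissive_thresholds(ped.samples)
        (c,) = find_candidates([s], ped, thr, IntervalSet())
        assert (c.parental_allele, c.mutant_allele) == ("G", "A")

    def test_shared_variant_flagged_as_cluster(self, ped):
        s = violation_site()
        s.calls["o2"] = call(("A", "G"), (8, 8))
        thr = permissive_thresholds(ped.samples)
        cands = find_candidates([s], ped, thr, IntervalSet())
        assert len(cands) == 2
        assert all(c.clustered for c in cands)

    def test_zero_parent_alt_option(self, ped):
        s = violation_site()
        s.calls["m"] = call(("A", "A"), (19, 1))  # minor AB 0.05 passes default rule
        thr = permissive_thresholds(ped.samples)
        assert len(find_candidates([s], ped, thr, IntervalSet())) == 1
        assert find_candidates(
            [s], ped, thr, IntervalSet(), require_zero_parent_alt=True
        ) == []


class TestConcordance:
    def test_matching_trio_concordant(self, ped):
        thr = permissive_thresholds(ped.samples)
        (cand,) = find_candidates([violation_site()], ped, thr, IntervalSet())
        secondary = {("c1", 100): violation_site()}
        (out,) = concordance_confirm([cand], secondary)
        assert out.concordance_status == "concordant"

    def test_secondary_homref_discordant(self, ped):
        thr = permissive_thresholds(ped.samples)
        (cand,) = find_candidates([violation_site()], ped, thr, IntervalSet())
        sec_site = violation_site()
        sec_site.calls["o1"] = call(("A", "A"), (20, 0))
        (out,) = concordance_confirm([cand], {("c1", 100): sec_site})
        assert out.concordance_status == "discordant"

    def test_absent_locus_discordant_with_warning(self, ped):
        thr = permissive_thresholds(ped.samples)
        (cand,) = find_candidates([violation_site()], ped, thr, IntervalSet())
        with pytest.warns(UserWarning, match="absent"):
            (out,) = concordance_confirm([cand], {})
        assert out.concordance_status == "discordant"


class TestMendelianConsistency:
    def test_consistent_trio(self):
        sites = [
            site(1, {"m": call(("A", "A"), (10, 0)), "f": call(("G", "G"), (0, 10)),
                     "o1": call(("A", "G"), (5, 5))}),
            site(2, {"m": call(("A", "G"), (5, 5)), "f": call(("A", "A"), (10, 0)),
                     "o1": call(("A", "A"), (10, 0))}),
        ]
        assert mendelian_consistency(sites, ("m", "f", "o1")) == 1.0

    def test_single_violation(self):
        sites = [site(1, {"m": call(("A", "A"), (10, 0)), "f": call(("A", "A"), (10, 0)),
                          "o1": call(("A", "T"), (5, 5))}, alts=("T",))]
        assert mendelian_consistency(sites, ("m", "f", "o1")) == 0.0

    def test_unrelated_offspring_detected(self):
        # true parents opposite homozygotes; an unrelated individual can be
        # homozygous where a real offspring must be heterozygous
        sites = [
            site(i, {"m": call(("A", "A"), (10, 0)), "f": call(("G", "G"), (0, 10)),
                     "o1": call(("A", "A"), (10, 0))})
            for i in range(1, 11)
        ]
        assert mendelian_consistency(sites, ("m", "f", "o1")) == 0.0

    def test_no_informative_sites_warns(self):
        sites = [site(1, {"m": call(("A", "G"), (5, 5)), "f": call(("A", "G"), (5, 5)),
                          "o1": call(("A", "G"), (5, 5))})]
        with pytest.warns(UserWarning):
            assert mendelian_consistency(sites, ("m", "f", "o1")) is None


def _cand(v, i=0):
    return CandidateDNM(
        contig="c1", position=100 + i, offspring_id="o1", parental_allele="A",
        mutant_allele="G", offspring_allele_balance=0.45,
        substitution_class="transition", concordance_status="concordant",
        validation_status=v,
    )


class TestValidationSummary:
    def test_reported_false_positive_rate(self):
        cands = (
            [_cand("confirmed", i) for i in range(4)]
            + [_cand("refuted", 10 + i) for i in range(7)]
            + [_cand("unvalidated", 20)]
        )
        out = summarize_validation(cands)
        assert out["n_candidates"] == 12
        assert out["n_validated"] == 11
        assert out["false_positive_rate_percent"] == pytest.approx(63.6, abs=0.05)

    def test_all_confirmed(self):
        out = summarize_validation([_cand("confirmed", i) for i in range(3)])
        assert out["false_positive_rate_percent"] == 0.0

    def test_all_refuted(self):
        out = summarize_validation([_cand("refuted", i) for i in range(3)])
        assert out["false_positive_rate_percent"] == 100.0

    def test_none_validated_warns(self):
        with pytest.warns(UserWarning):
            out = summarize_validation([_cand("untested")])
        assert out["false_positive_rate_percent"] is None


def test_candidates_tsv_round_trip(tmp_path):
    cands = [_cand("confirmed"), _cand("unvalidated", 5)]
    cands[1].clustered = True
    path = tmp_path / "c.tsv"
    write_candidates_tsv(cands, path)
    back = read_candidates_tsv(path)
    assert [c.key for c in back] == [c.key for c in cands]
    assert back[1].clustered and not back[0].clustered
    assert back[0].validation_status == "confirmed"
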