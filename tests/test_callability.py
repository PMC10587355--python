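import numpy as np
import pytest

from dnmpipe.callability import (
    ThresholdSet,
    build_exclusion_mask,
    classify_callable,
    count_callable,
    derive_thresholds,
    find_high_confidence_hets,
    kmer_mappability,
    masked_fraction,
)
from dnmpipe.pedigree_data import IntervalSet, Pedigree
from helpers import call, permissive_thresholds, site


def oracle_mappability(seq, k, e):
    """All-pairs Hamming-distance scan, written independently of the
    implementation (pure python, no vectorisation)."""
    kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    scores = []
    for a in kmers:
        n = 0
        for b in kmers:
            if sum(x != y for x, y in zip(a, b)) <= e:
                n += 1
        scores.append(1.0 / n)
    return scores


class TestKmerMappability:
    def test_repeated_kmer_halves_score(self):
        # ACGTACGT, k=4: ACGT occurs at positions 0 and 4
        scores = kmer_mappability("ACGTACGT", 4, 0)
        assert scores.tolist() == [0.5, 1.0, 1.0, 1.0, 0.5]

    def test_unique_sequence_scores_one(self):
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        scores = kmer_mappability(seq, 8, 0)
        assert scores.tolist() == oracle_mappability(seq, 8, 0)

    def test_saturation_when_mismatch_budget_exceeds_k(self):
        seq = "ACGTACGTACGT"
        n = len(seq) - 4 + 1
        assert np.allclose(kmer_mappability(seq, 4, 4), 1.0 / n)

    @pytest.mark.parametrize("e", [1, 2])
    def test_mismatch_tolerant_matches_oracle(self, e):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        seq = seq + seq[:30]  # engineered repeat
        assert np.allclose(kmer_mappability(seq, 8, e), oracle_mappability(seq, 8, e))

    def test_short_sequence_fatal(self):
        with pytest.raises(ValueError):
            kmer_mappability("ACG", 5, 0)


class TestMaskedFraction:
    def test_reported_assembly_coverage(self):
        assert masked_fraction(1_838_924_616, 4_149_461_884) == 44.32

    def test_bounds(self):
        assert masked_fraction(0, 100) == 0.0
        assert masked_fraction(100, 100) == 100.0
        with pytest.raises(ValueError):
            masked_fraction(101, 100)
        with pytest.raises(ValueError):
            masked_fraction(1, 0)


class TestExclusionMask:
    def test_union_merges(self):
        rep = IntervalSet.from_pairs([("c1", 0, 100)])
        lm = IntervalSet.from_pairs([("c1", 50, 200)])
        assert build_exclusion_mask(rep, lm).intervals("c1").tolist() == [[0, 200]]

    def test_both_empty(self):
        assert build_exclusion_mask(IntervalSet(), IntervalSet()).is_empty()

    def test_disjoint_sorted(self):
        rep = IntervalSet.from_pairs([("c1", 100, 150)])
        lm = IntervalSet.from_pairs([("c1", 0, 50)])
        assert build_exclusion_mask(rep, lm).intervals("c1").tolist() == [[0, 50], [100, 150]]


@pytest.fixture
def trio_ped():
    return Pedigree("m", "f", ("o1", "o2"))


def hc_pattern_site(pos, off_ab_depths=((7, 7), (6, 8)), father_ad=(0, 12)):
    return site(pos, {
        "m": call(("A", "A"), (12, 0)),
        "f": call(("G", "G"), father_ad),
        "o1": call(("A", "G"), off_ab_depths[0]),
        "o2": call(("A", "G"), off_ab_depths[1]),
    })


class TestHighConfidenceHets:
    def test_textbook_pattern_retained(self, trio_ped):
        sites = [hc_pattern_site(10)]
        assert len(find_high_confidence_hets(sites, trio_ped, IntervalSet())) == 1

    def test_offspring_balance_below_threshold_excluded(self, trio_ped):
        sites = [hc_pattern_site(10, off_ab_depths=((4, 16), (7, 7)))]  # AB 0.20
        assert find_high_confidence_hets(sites, trio_ped, IntervalSet()) == []

    def test_het_parent_excluded(self, trio_ped):
        s = hc_pattern_site(10)
        s.calls["f"] = call(("A", "G"), (6, 6))
        assert find_high_confidence_hets([s], trio_ped, IntervalSet()) == []

    def test_same_allele_parents_excluded(self, trio_ped):
        s = hc_pattern_site(10)
        s.calls["f"] = call(("A", "A"), (12, 0))
        assert find_high_confidence_hets([s], trio_ped, IntervalSet()) == []

    def test_masked_site_excluded(self, trio_ped):
        mask = IntervalSet.from_pairs([("c1", 0, 50)])
        assert find_high_confidence_hets([hc_pattern_site(10)], trio_ped, mask) == []

    def test_low_gq_excluded(self, trio_ped):
        s = hc_pattern_site(10)
        s.calls["o1"] = call(("A", "G"), (7, 7), gq=15)
        assert find_high_confidence_hets([s], trio_ped, IntervalSet()) == []


class TestDeriveThresholds:
    def test_linear_interpolation_percentiles(self, trio_ped):
        sites = [hc_pattern_site(i + 1) for i in range(101)]
        for i, s in enumerate(sites):
            s.base_quality_rank_sum = float(i)
            s.read_position_rank_sum = float(i)
            s.mapping_quality = 40.0 + 20.0 * i / 100.0
        thr = derive_thresholds(sites, trio_ped)
        assert thr.base_quality_rank_sum == pytest.approx((5.0, 95.0))
        assert thr.read_position_rank_sum == pytest.approx((5.0, 95.0))
        # MQ keeps the lower bound only
        assert thr.mapping_quality_low == pytest.approx(41.0)

    def test_constant_annotation_degenerate_bounds(self, trio_ped):
        sites = [hc_pattern_site(i + 1) for i in range(100)]
        thr = derive_thresholds(sites, trio_ped)
        assert thr.base_quality_rank_sum == (0.0, 0.0)

    def test_too_few_sites_fatal(self, trio_ped):
        with pytest.raises(ValueError, match="37"):
            derive_thresholds([hc_pattern_site(i + 1) for i in range(37)], trio_ped)

    def test_per_sample_depth_bands(self, trio_ped):
        sites = [hc_pattern_site(i + 1) for i in range(100)]
        thr = derive_thresholds(sites, trio_ped)
        assert thr.depth["m"] == (12.0, 12.0)
        assert thr.depth["o2"] == (14.0, 14.0)


class TestClassifyCallable:
    def _thresholds(self):
        return ThresholdSet(
            base_quality_rank_sum=(-2.0, 2.0),
            read_position_rank_sum=(-2.0, 2.0),
            mapping_quality_low=50.0,
            quality_by_depth_low=10.0,
            depth={"m": (8, 16), "f": (8, 16), "o1": (8, 16), "o2": (5, 13)},
        )

    def test_mq_below_bound_fails(self):
        s = hc_pattern_site(10)
        s.mapping_quality = 45.0
        assert not classify_callable(s, ("m", "f", "o1"), self._thresholds(), IntervalSet())

    def test_per_trio_depth_band(self):
        s = hc_pattern_site(10)  # o2 depth 14 exceeds its band (5, 13)
        thr = self._thresholds()
        assert classify_callable(s, ("m", "f", "o1"), thr, IntervalSet())
        assert not classify_callable(s, ("m", "f", "o2"), thr, IntervalSet())

    def test_masked_site_fails(self):
        mask = IntervalSet.from_pairs([("c1", 9, 10)])
        assert not classify_callable(
            hc_pattern_site(10), ("m", "f", "o1"), self._thresholds(), mask
        )

    def test_missing_annotation_passes(self):
        s = hc_pattern_site(10)
        s.base_quality_rank_sum = None
        s.quality_by_depth = None
        assert classify_callable(s, ("m", "f", "o1"), self._thresholds(), IntervalSet())

    def test_missing_call_fails(self):
        s = hc_pattern_site(10)
        s.calls["m"] = call(None)
        assert not classify_callable(s, ("m", "f", "o1"), self._thresholds(), IntervalSet())

    def test_multiallelic_site_never_callable(self, trio_ped):
        s = hc_pattern_site(10)
        s.alt_alleles = ("G", "T")
        assert not classify_callable(s, ("m", "f", "o1"), self._thresholds(), IntervalSet())


class TestCountCallable:
    def test_summed_over_trios(self, trio_ped):
        sites = [hc_pattern_site(10)]
        thr = permissive_thresholds(trio_ped.samples)
        counts, total = count_callable(sites, trio_ped, thr, IntervalSet())
        assert counts == {"o1": 1, "o2": 1}
        assert total == 2  # one genomic site, counted once per trio

    def test_no_callable_sites(self, trio_ped):
        thr = permissive_thresholds(trio_ped.samples, depth=(1000, 2000))
        counts, total = count_callable([hc_pattern_site(10)], trio_ped, thr, IntervalSet())
        assert total == 0


class TestFilterChainProperties:
    """Properties checked on a simulated pedigree (session fixture)."""

    def test_tightening_thresholds_never_gains_sites(self, small_run):
        import dataclasses

        thr = small_run.thresholds
        cp = small_run.calls_primary
        pileups = small_run.pileups
        rng = np.random.default_rng(0)
        base_counts = np.array(list(small_run.callable_counts.values()))

        def recount(t):
            # independent recount straight from the arrays
            from dnmpipe.synthetic import gq_homref

            L = small_run.config.genome_length
            samples = pileups.samples
            member = []
            for s, name in enumerate(samples):
                d = pileups.depth[s]
                gq = gq_homref(d, cp.eps_model, cp.log_priors).astype(np.int32)
                rows = np.flatnonzero(cp.err_sample == s)
                gq[cp.err_gpos[rows]] = cp.err_gq[rows]
                gq[cp.var_gpos] = cp.GQ[s]
                lo, hi = t.depth[name]
                member.append((d > 0) & (gq >= 20) & (d >= lo) & (d <= hi))
            from dnmpipe.vectorized import _mask_array

            mask_arr = _mask_array(small_run.mask, small_run.config)
            sp = (pileups.mq >= t.mapping_quality_low) & ~mask_arr
            emitted = cp.has_alt
            ann = (
                (cp.bq >= t.base_quality_rank_sum[0]) & (cp.bq <= t.base_quality_rank_sum[1])
                & (cp.rp >= t.read_position_rank_sum[0]) & (cp.rp <= t.read_position_rank_sum[1])
                & (cp.mq_var >= t.mapping_quality_low) & (cp.qd >= t.quality_by_depth_low)
                & ~mask_arr[cp.var_gpos]
            )
            sp[cp.var_gpos[emitted]] = ann[emitted]
            return np.array([
                int((sp & member[0] & member[1] & member[2 + k]).sum())
                for k in range(small_run.config.n_offspring)
            ])

        assert (recount(thr) == base_counts).all()
        for _ in range(8):
            t = dataclasses.replace(
                thr,
                base_quality_rank_sum=(
                    thr.base_quality_rank_sum[0] + rng.uniform(0, 0.5),
                    thr.base_quality_rank_sum[1] - rng.uniform(0, 0.5),
                ),
                mapping_quality_low=thr.mapping_quality_low + rng.uniform(0, 1),
                quality_by_depth_low=thr.quality_by_depth_low + rng.uniform(0, 2),
                depth={
                    s: (lo + rng.uniform(0, 2), hi - rng.uniform(0, 2))
                    for s, (lo, hi) in thr.depth.items()
                },
            )
            tightened = recount(t)
            assert (tightened <= base_counts).all()

    def test_percentile_coverage_on_hc_sites(self, small_run):
        # ~90% of each two-sided annotation's hc values lie within its bounds
        cp = small_run.calls_primary
        thr = small_run.thresholds
        from dnmpipe.vectorized import _minor_ab

        ab = _minor_ab(cp.AD_ref, cp.AD_alt)
        gt, gq = cp.GT, cp.GQ
        with np.errstate(invalid="ignore"):
            hc_mask = (
                cp.has_alt
                & (gt >= 0).all(0) & (gq >= 20).all(0)
                & (((gt[0] == 0) & (gt[1] == 2)) | ((gt[0] == 2) & (gt[1] == 0)))
                & (ab[0] < 0.1) & (ab[1] < 0.1)
                & (gt[2:] == 1).all(0) & (ab[2:] >= 0.25).all(0)
            )
        hc_mask &= ~_mask_of(small_run)[cp.var_gpos]
        assert hc_mask.sum() == thr.n_sites
        for values, (lo, hi) in (
            (cp.bq[hc_mask], thr.base_quality_rank_sum),
            (cp.rp[hc_mask], thr.read_position_rank_sum),
        ):
            frac = np.mean((values >= lo) & (values <= hi))
            assert 0.84 <= frac <= 0.96

    def test_hc_sites_passing_thresholds_are_callable_everywhere(self, small_run, emitted):
        from dnmpipe.callability import (
            classify_callable,
            find_high_confidence_hets,
            site_filters_pass,
        )
        from dnmpipe.pedigree_data import load_intervals, load_pedigree, load_sites

        ped = load_pedigree(emitted["pedigree_tsv"])
        mask = load_intervals(emitted["repeats_bed"]).union(
            load_intervals(emitted["mappability_bed"])
        )
        sites = list(load_sites(emitted["primary_vcf"], ped))
        hc = find_high_confidence_hets(sites, ped, mask)
        thr = small_run.thresholds
        for s in hc:
            if not site_filters_pass(s, thr):
                continue
            if any(
                not (thr.depth[sm][0] <= s.calls[sm].total_depth <= thr.depth[sm][1])
                for sm in ped.samples
            ):
                continue
            for trio in ped.trios():
                assert classify_callable(s, trio, thr, mask)


def _mask_of(run):
    from dnmpipe.vectorized import _mask_array

    return _mask_array(run.mask, run.config)
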