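import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from dnmpipe.synthetic import (
    PileupSet,
    SimConfig,
    call_from_counts,
    call_genotypes,
    caller_log_priors,
    emit,
    gq_homref,
    simulate_founders,
    simulate_pedigree,
    substream,
    transmit,
)

PHRED = 10.0 / np.log(10.0)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, target_pi=0.3)
        with pytest.raises(ValueError):
            SimConfig(seed=1, error_rate=-0.1)
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_offspring=0)

    def test_coordinate_round_trip(self):
        cfg = SimConfig(seed=1, genome_length=1000, n_contigs=3)
        for gpos in (0, 332, 333, 999):
            contig, local = cfg.locus(gpos)
            assert cfg.global_position(contig, local) == gpos

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, genome_length=5000, target_pi=0.01)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestFounders:
    def test_heterozygosity_near_target(self):
        cfg = SimConfig(seed=21, genome_length=100_000, target_pi=0.01)
        f = simulate_founders(cfg)
        het = (f.mother_h[0] != f.mother_h[1]).sum()
        expected = cfg.target_pi * cfg.genome_length
        se = np.sqrt(expected)
        assert abs(het - expected) < 3 * se

    def test_zero_pi_gives_identical_homozygous_parents(self):
        cfg = SimConfig(seed=21, genome_length=50_000, target_pi=0.0)
        f = simulate_founders(cfg)
        assert f.var_pos.size == 0

    def test_seed_determinism(self):
        cfg = SimConfig(seed=4, genome_length=20_000, target_pi=0.01)
        a, b = simulate_founders(cfg), simulate_founders(cfg)
        assert np.array_equal(a.var_pos, b.var_pos)
        assert np.array_equal(a.mother_h, b.mother_h)
        assert a.repeat_mask == b.repeat_mask

    def test_repeat_mask_covers_requested_fraction(self):
        cfg = SimConfig(seed=4, genome_length=100_000, repeat_fraction=0.2)
        f = simulate_founders(cfg)
        assert f.repeat_mask.total_bases() == pytest.approx(20_000, rel=0.05)


class TestTransmission:
    def test_mendelian_construction(self):
        cfg = SimConfig(seed=8, genome_length=50_000, target_pi=0.02, n_offspring=4,
                        mu_true=1e-4)
        sim = simulate_pedigree(cfg)
        dnm_keys = sim.truth.dnm_keys()
        samples = cfg.sample_ids
        for j in range(cfg.n_offspring):
            s = 2 + j
            for hap, parent in ((0, 0), (1, 1)):
                child = sim.H[s, hap]
                ok = (sim.H[parent, 0] == child) | (sim.H[parent, 1] == child)
                for col in np.flatnonzero(~ok).tolist():
                    contig, local = cfg.locus(int(sim.pos[col]))
                    assert (contig, local + 1, samples[s]) in dnm_keys

    def test_planted_counts_poisson(self):
        # total planted DNMs per pedigree ~ Poisson(2 mu L n_off)
        cfg_base = dict(genome_length=50_000, target_pi=0.0, n_offspring=3, mu_true=1e-5)
        lam = 2 * 1e-5 * 50_000 * 3
        counts = []
        for seed in range(80):
            sim = transmit(simulate_founders(SimConfig(seed=seed, **cfg_base)))
            counts.append(len(sim.truth.dnms))
        counts = np.array(counts)
        edges = [0, 1, 2, 3, 4, np.inf]
        observed = np.histogram(counts, bins=edges)[0]
        probs = np.diff([stats.poisson.cdf(e - 1, lam) if np.isfinite(e) else 1.0
                         for e in edges], prepend=0)[1:]
        chi2 = stats.chisquare(observed, probs * len(counts))
        assert chi2.pvalue > 0.01

    def test_zero_rate_plants_nothing(self):
        cfg = SimConfig(seed=8, genome_length=50_000, mu_true=0.0)
        assert simulate_pedigree(cfg).truth.dnms == []

    def test_origin_recorded(self):
        cfg = SimConfig(seed=8, genome_length=50_000, target_pi=0.0, mu_true=1e-4,
                        n_offspring=2)
        sim = simulate_pedigree(cfg)
        assert sim.truth.dnms
        assert {d.origin for d in sim.truth.dnms} <= {"maternal", "paternal"}


class TestCallerModel:
    def test_clean_homref_gq_closed_form(self):
        # (20, 0) at model error 1e-3: margin over het is 20 ln(0.999/0.5)
        gt, gq = call_from_counts(np.array([20]), np.array([0]), 1e-3, np.zeros(3))
        assert gt[0] == 0
        expect = round(PHRED * 20 * np.log(0.999 / 0.5))
        assert gq[0] == expect == 60
        assert gq_homref(np.array([20]), 1e-3, np.zeros(3))[0] == gq[0]

    def test_balanced_het_under_both_profiles(self):
        for profile in ("primary", "secondary"):
            lp = caller_log_priors(profile, 0.002)
            gt, gq = call_from_counts(np.array([10]), np.array([10]), 1e-3, lp)
            assert gt[0] == 1
            assert gq[0] > 20

    def test_gq_capped(self):
        gt, gq = call_from_counts(np.array([60]), np.array([0]), 1e-3, np.zeros(3))
        assert gq[0] == 99

    def test_profiles_disagree_at_marginal_evidence(self):
        # 1 alt read in 5: flat prior calls het, het-downweighting prior hom-ref
        gt_p, _ = call_from_counts(np.array([4]), np.array([1]), 1e-3,
                                   caller_log_priors("primary", 0.002))
        gt_s, _ = call_from_counts(np.array([4]), np.array([1]), 1e-3,
                                   caller_log_priors("secondary", 0.002))
        assert gt_p[0] == 1 and gt_s[0] == 0

    def test_no_reads_is_uninformative(self):
        gt, gq = call_from_counts(np.array([0]), np.array([0]), 1e-3, np.zeros(3))
        assert gt[0] == 0 and gq[0] == 0


class TestPileups:
    def test_het_allele_counts_binomial(self):
        cfg = SimConfig(seed=12, genome_length=20_000, target_pi=0.02, n_offspring=1,
                        mu_true=0.0, mean_depth_parents=40, mean_depth_offspring=40,
                        error_rate=0.0)
        sim = simulate_pedigree(cfg)
        p = PileupSet(sim)
        het = (sim.H[0, 0] != sim.H[0, 1])
        fracs = p.var_alt_obs[0, het] / np.maximum(
            p.var_alt_obs[0, het] + p.var_ref_obs[0, het], 1
        )
        n = het.sum()
        assert n > 50
        assert fracs.mean() == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(40 * n) * 6)
        hom = (sim.H[0].sum(axis=0) == 2)
        assert (p.var_ref_obs[0, hom] == 0).all()  # error-free hom-alt: no ref reads

    def test_fragments_cosegregate_without_error(self):
        cfg = SimConfig(seed=14, genome_length=30_000, target_pi=0.05, n_offspring=2,
                        mu_true=1e-4, error_rate=0.0, fragment_length=1500,
                        fixed_depth=True)
        sim = simulate_pedigree(cfg)
        p = PileupSet(sim)
        assert p.fragments
        idx = {s: i for i, s in enumerate(p.samples)}
        for frag in p.fragments[:50]:
            sample = frag.fragment_id.split(":")[0]
            s = idx[sample]
            matches = []
            for hap in (0, 1):
                ok = True
                for contig, pos1, allele in frag.observations:
                    gpos = cfg.global_position(contig, pos1 - 1)
                    col = int(np.searchsorted(sim.pos, gpos))
                    from dnmpipe.synthetic import BASES

                    want = str(BASES[sim.alt[col] if sim.H[s, hap, col] else sim.ref[col]])
                    if want != allele:
                        ok = False
                        break
                matches.append(ok)
            assert any(matches)  # one underlying haplotype per fragment


@pytest.fixture(scope="module")
def tiny(tmp_path_factory):
    cfg = SimConfig(seed=33, genome_length=4000, target_pi=0.02, n_offspring=2,
                    mu_true=2e-4, mean_depth_parents=25, mean_depth_offspring=20,
                    error_rate=1e-3)
    sim = simulate_pedigree(cfg)
    p = PileupSet(sim)
    cp = call_genotypes(p, "primary")
    cs = call_genotypes(p, "secondary")
    out1 = tmp_path_factory.mktemp("emit1")
    out2 = tmp_path_factory.mktemp("emit2")
    paths1 = emit(sim, p, cp, cs, out1)
    # full second run from the seed alone
    sim2 = simulate_pedigree(cfg)
    p2 = PileupSet(sim2)
    paths2 = emit(sim2, p2, call_genotypes(p2, "primary"),
                  call_genotypes(p2, "secondary"), out2)
    return paths1, paths2, cfg, sim


class TestEmit:
    def test_file_set(self, tiny):
        paths1, _, cfg, sim = tiny
        assert len(paths1) == 8
        header = next(
            l for l in Path(paths1["primary_vcf"]).read_text().splitlines()
            if l.startswith("#CHROM")
        )
        assert len(header.split("\t")) == 9 + 2 + cfg.n_offspring
        truth_rows = Path(paths1["truth_tsv"]).read_text().strip().splitlines()
        assert len(truth_rows) - 1 == len(sim.truth.dnms)

    def test_byte_identical_reruns(self, tiny):
        paths1, paths2, _, _ = tiny
        for key in paths1:
            h1 = hashlib.sha256(Path(paths1[key]).read_bytes()).hexdigest()
            h2 = hashlib.sha256(Path(paths2[key]).read_bytes()).hexdigest()
            assert h1 == h2, key

    def test_substreams_are_independent(self):
        a = substream(1, "founders").integers(0, 100, 5)
        b = substream(1, "pileups").integers(0, 100, 5)
        c = substream(1, "founders").integers(0, 100, 5)
        assert np.array_equal(a, c)
        assert not np.array_equal(a, b)
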