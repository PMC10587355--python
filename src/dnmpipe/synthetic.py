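"""Synthetic pedigree generator.

Simulates the statistical structure the pipeline assumes, with ground
truth: two diploid founders at a target heterozygosity, Mendelian
transmission with recombination, de novo mutations planted at a known rate
with recorded parental origin, per-site read pileups with depth and
sequencing error, and two slightly different emulated genotype callers with
realistic quality annotations.

The founder model places a fraction 2*pi of positions as population
polymorphisms at allele frequency 0.5 and draws each founder allele
independently, so expected per-individual heterozygosity equals pi exactly.
Every random stage draws from an independent named substream of the master
seed, so stages are independently reproducible.
"""
from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .callability import kmer_mappability, low_mappability_intervals
from .pedigree_data import IntervalSet, Pedigree, write_pedigree
from .phasing import ReadFragment

__all__ = [
    "SimConfig",
    "PlantedDNM",
    "TruthTable",
    "FounderGenomes",
    "PedigreeSim",
    "PileupSet",
    "CallSet",
    "substream",
    "simulate_founders",
    "transmit",
    "simulate_pedigree",
    "simulate_pileups",
    "call_genotypes",
    "gq_homref",
    "call_from_counts",
    "caller_log_priors",
    "emit",
    "BASES",
]

BASES = np.array(["A", "C", "G", "T"])
_PHRED = 10.0 / np.log(10.0)
_LOG_HALF = float(np.log(0.5))
GQ_CAP = 99
MIN_CALLER_ERROR = 1e-4  # caller's error model floor; a caller never assumes error-free reads


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random substream of a master seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are the reference study conditions for end-to-end validation:
    a 10 Mb diploid genome, founder heterozygosity pi = 0.002, nine
    offspring, a true rate of 1e-7 per bp per generation, parent/offspring
    mean depths 40x/30x and a 1e-3 per-base error rate. ``fixed_depth``
    replaces Poisson depth with its (rounded) mean — the idealised
    saturating-coverage mode used for exact-recovery validation.
    """

    seed: int
    genome_length: int = 10_000_000
    n_contigs: int = 1
    target_pi: float = 0.002
    n_offspring: int = 9
    mu_true: float = 1e-7
    mean_depth_parents: float = 40.0
    mean_depth_offspring: float = 30.0
    error_rate: float = 1e-3
    repeat_fraction: float = 0.10
    recombination_rate: float = 1.0
    fragment_length: int = 350
    ts_tv_kappa: float = 2.0
    fixed_depth: bool = False
    mappability_k: int = 31

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("target_pi", "mu_true", "error_rate", "repeat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.target_pi > 0.25:
            raise ValueError("target_pi > 0.25 not representable at allele frequency 0.5")
        for name in ("genome_length", "n_contigs", "n_offspring", "fragment_length",
                     "mappability_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_contigs > self.genome_length:
            raise ValueError("more contigs than bases")

    # -- coordinate helpers -------------------------------------------------
    def contig_bounds(self) -> list[tuple[str, int, int]]:
        """(name, global_start, global_end) with near-equal contig lengths."""
        base = self.genome_length // self.n_contigs
        bounds = []
        start = 0
        for i in range(self.n_contigs):
            end = start + base if i < self.n_contigs - 1 else self.genome_length
            bounds.append((f"contig_{i + 1}", start, end))
            start = end
        return bounds

    def contig_lengths(self) -> dict[str, int]:
        return {name: end - start for name, start, end in self.contig_bounds()}

    def locus(self, gpos: int) -> tuple[str, int]:
        """Global 0-based position -> (contig, local 0-based position)."""
        for name, start, end in self.contig_bounds():
            if start <= gpos < end:
                return name, gpos - start
        raise ValueError(f"position {gpos} outside genome of length {self.genome_length}")

    def global_position(self, contig: str, local0: int) -> int:
        for name, start, end in self.contig_bounds():
            if name == contig:
                if not 0 <= local0 < end - start:
                    raise ValueError(f"{contig}:{local0} outside contig")
                return start + local0
        raise ValueError(f"unknown contig {contig}")

    @property
    def sample_ids(self) -> list[str]:
        return ["mother", "father"] + [f"off{i + 1}" for i in range(self.n_offspring)]

    def pedigree(self) -> Pedigree:
        return Pedigree("mother", "father", tuple(self.sample_ids[2:]))

    def mean_depths(self) -> np.ndarray:
        return np.array(
            [self.mean_depth_parents, self.mean_depth_parents]
            + [self.mean_depth_offspring] * self.n_offspring
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class PlantedDNM:
    contig: str
    position: int  # 1-based
    offspring_id: str
    ref: str
    alt: str
    origin: str  # maternal | paternal


@dataclass
class TruthTable:
    """Simulator ground truth for recovery scoring."""

    dnms: list[PlantedDNM]
    n_founder_sites: int
    spikes: list[dict] = field(default_factory=list)

    def dnm_keys(self) -> set[tuple[str, int, str]]:
        return {(d.contig, d.position, d.offspring_id) for d in self.dnms}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\toffspring_id\tref\talt\torigin\n")
            for d in self.dnms:
                fh.write(
                    f"{d.contig}\t{d.position}\t{d.offspring_id}\t{d.ref}\t{d.alt}\t{d.origin}\n"
                )


def _sample_distinct_positions(
    rng: np.random.Generator, length: int, n: int, forbidden: set[int] | None = None
) -> np.ndarray:
    """n distinct uniform positions in [0, length), avoiding ``forbidden``."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    forbidden = forbidden or set()
    if n + len(forbidden) > length:
        raise ValueError("not enough free positions")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(0, length, size=2 * (n - len(chosen)) + 8)
        for p in draw.tolist():
            if p not in forbidden and p not in chosen:
                chosen.add(p)
                if len(chosen) == n:
                    break
    return np.sort(np.fromiter(chosen, dtype=np.int64, count=n))


def _mutate(rng: np.random.Generator, ref_codes: np.ndarray, kappa: float) -> np.ndarray:
    """Alternative base codes under a transition/transversion weight kappa.

    P(transition) = kappa / (kappa + 2); the two transversions split the rest.
    """
    transition = (ref_codes + 2) % 4  # A<->G, C<->T in ACGT coding
    u = rng.random(ref_codes.shape)
    p_ts = kappa / (kappa + 2.0)
    # transversion partners: the two bases of the other purine/pyrimidine class
    tv_first = (ref_codes + 1) % 4
    tv_second = (ref_codes + 3) % 4
    out = np.where(u < p_ts, transition,
                   np.where(u < p_ts + (1 - p_ts) / 2, tv_first, tv_second))
    return out.astype(np.uint8)


@dataclass
class FounderGenomes:
    config: SimConfig
    var_pos: np.ndarray  # global 0-based, sorted; >=1 alt allele among founders
    ref: np.ndarray  # uint8 codes
    alt: np.ndarray
    mother_h: np.ndarray  # (2, n_var) 0/1 alt indicators
    father_h: np.ndarray
    repeat_mask: IntervalSet


def simulate_founders(config: SimConfig) -> FounderGenomes:
    """Two diploid founders plus the repeat-mask annotation.

    A fraction 2*pi of positions is polymorphic at frequency 0.5; founder
    alleles are iid Bernoulli(0.5) there, giving expected per-individual
    heterozygosity pi. Positions where no founder carries the alternative
    allele are monomorphic in the pedigree and dropped from the variant map.
    """
    rng = substream(config.seed, "founders")
    L = config.genome_length
    n_poly = int(rng.binomial(L, min(2.0 * config.target_pi, 1.0)))
    pos = _sample_distinct_positions(rng, L, n_poly)
    hap = rng.integers(0, 2, size=(4, n_poly), dtype=np.uint8)
    keep = hap.any(axis=0)
    pos, hap = pos[keep], hap[:, keep]
    ref = rng.integers(0, 4, size=pos.size, dtype=np.uint8)
    alt = _mutate(rng, ref, config.ts_tv_kappa)

    # repeat annotation: disjoint blocks on a fixed grid covering repeat_fraction
    block = max(200, min(2000, L // 50)) if L >= 400 else max(1, L // 4)
    n_grid = L // block
    n_blocks = int(round(config.repeat_fraction * L / block))
    n_blocks = min(n_blocks, n_grid)
    pairs: list[tuple[str, int, int]] = []
    if n_blocks > 0:
        grid = rng.choice(n_grid, size=n_blocks, replace=False)
        bounds = config.contig_bounds()
        for g in np.sort(grid):
            s, e = int(g) * block, (int(g) + 1) * block
            for name, cstart, cend in bounds:
                if s < cend and e > cstart:
                    pairs.append((name, max(s, cstart) - cstart, min(e, cend) - cstart))
    return FounderGenomes(
        config=config,
        var_pos=pos,
        ref=ref,
        alt=alt,
        mother_h=hap[:2],
        father_h=hap[2:],
        repeat_mask=IntervalSet.from_pairs(pairs),
    )


@dataclass
class PedigreeSim:
    """Founders + offspring haplotypes over the full variant map (founder
    polymorphisms and planted DNMs), with ground truth."""

    config: SimConfig
    founders: FounderGenomes
    pos: np.ndarray  # global 0-based, sorted (founder variants + DNMs)
    ref: np.ndarray
    alt: np.ndarray
    H: np.ndarray  # (n_samples, 2, n_sites) alt indicators; hap 0 maternal-derived
    truth: TruthTable
    _seq: np.ndarray | None = None

    @property
    def pedigree(self) -> Pedigree:
        return self.config.pedigree()

    def sequence_codes(self) -> np.ndarray:
        """Reference base codes for the whole genome (lazily generated;
        variant-map positions carry their recorded ref base)."""
        if self._seq is None:
            rng = substream(self.config.seed, "sequence")
            seq = rng.integers(0, 4, size=self.config.genome_length, dtype=np.uint8)
            seq[self.pos] = self.ref
            self._seq = seq
        return self._seq


def _gamete(
    rng: np.random.Generator,
    parent_h: np.ndarray,
    var_pos: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """One recombined haploid gamete sampled from a parent's two haplotypes."""
    out = np.empty(var_pos.size, dtype=np.uint8)
    for name, start, end in config.contig_bounds():
        i0, i1 = np.searchsorted(var_pos, [start, end])
        start_hap = int(rng.integers(0, 2))
        n_cross = int(rng.poisson(config.recombination_rate))
        if n_cross:
            xpos = np.sort(rng.integers(start, end, size=n_cross))
            hap_idx = (start_hap + np.searchsorted(xpos, var_pos[i0:i1], side="right")) % 2
        else:
            hap_idx = np.full(i1 - i0, start_hap)
        out[i0:i1] = parent_h[hap_idx, np.arange(i0, i1)]
    return out


def transmit(founders: FounderGenomes, config: SimConfig | None = None) -> PedigreeSim:
    """Mendelian transmission with recombination plus planted DNMs.

    Each offspring receives one recombined gamete per parent; DNMs are
    planted per gamete as Poisson(mu_true * L) at uniform non-polymorphic
    positions, mutant base drawn with transition weight ts_tv_kappa, and the
    gamete of origin recorded in the truth table.
    """
    config = config or founders.config
    rng = substream(config.seed, "transmit")
    n_var = founders.var_pos.size
    gametes: list[tuple[np.ndarray, np.ndarray]] = []
    dnm_records: list[tuple[int, int, int]] = []  # (gpos, offspring_idx, origin 0=mat)
    taken: set[int] = set(founders.var_pos.tolist())
    for j in range(config.n_offspring):
        gm = _gamete(rng, founders.mother_h, founders.var_pos, config)
        gf = _gamete(rng, founders.father_h, founders.var_pos, config)
        gametes.append((gm, gf))
        for origin in (0, 1):
            n_dnm = int(rng.poisson(config.mu_true * config.genome_length))
            new = _sample_distinct_positions(rng, config.genome_length, n_dnm, taken)
            taken.update(new.tolist())
            for p in new.tolist():
                dnm_records.append((p, j, origin))

    dnm_records.sort()
    dnm_pos = np.array([r[0] for r in dnm_records], dtype=np.int64)
    seq_rng = substream(config.seed, "transmit-dnm-bases")
    dnm_ref = seq_rng.integers(0, 4, size=dnm_pos.size, dtype=np.uint8)
    dnm_alt = _mutate(seq_rng, dnm_ref, config.ts_tv_kappa)

    all_pos = np.concatenate([founders.var_pos, dnm_pos])
    order = np.argsort(all_pos, kind="stable")
    all_pos = all_pos[order]
    ref = np.concatenate([founders.ref, dnm_ref])[order]
    alt = np.concatenate([founders.alt, dnm_alt])[order]

    n_samples = 2 + config.n_offspring
    H = np.zeros((n_samples, 2, all_pos.size), dtype=np.uint8)
    founder_cols = np.searchsorted(all_pos, founders.var_pos)
    H[0][:, founder_cols] = founders.mother_h
    H[1][:, founder_cols] = founders.father_h
    for j, (gm, gf) in enumerate(gametes):
        H[2 + j][0, founder_cols] = gm
        H[2 + j][1, founder_cols] = gf

    samples = config.sample_ids
    dnms = []
    for (gpos, j, origin), rbase, abase in zip(
        dnm_records, dnm_ref.tolist(), dnm_alt.tolist()
    ):
        col = int(np.searchsorted(all_pos, gpos))
        H[2 + j, origin, col] = 1
        contig, local = config.locus(gpos)
        dnms.append(
            PlantedDNM(
                contig=contig,
                position=local + 1,
                offspring_id=samples[2 + j],
                ref=str(BASES[rbase]),
                alt=str(BASES[abase]),
                origin="maternal" if origin == 0 else "paternal",
            )
        )
    truth = TruthTable(dnms=dnms, n_founder_sites=n_var)
    return PedigreeSim(
        config=config, founders=founders, pos=all_pos, ref=ref, alt=alt, H=H, truth=truth
    )


def simulate_pedigree(config: SimConfig) -> PedigreeSim:
    """simulate_founders + transmit in one call."""
    return transmit(simulate_founders(config), config)


class PileupSet:
    """Per-site per-sample read counts over the simulated genome.

    Dense depth matrix, exact base counts at variant-map positions, sparse
    error-read records at invariant positions, and read fragments around
    planted DNMs for phasing. Spiked-in variants are stored separately and
    merged at genotype-calling time.
    """

    def __init__(self, sim: PedigreeSim):
        self.sim = sim
        config = sim.config
        self.samples = config.sample_ids
        rng = substream(config.seed, "pileups")
        S = len(self.samples)
        L = config.genome_length
        means = config.mean_depths()
        if config.fixed_depth:
            self.depth = np.tile(
                np.rint(means).astype(np.int32)[:, None], (1, L)
            )
        else:
            self.depth = rng.poisson(means[:, None], size=(S, L)).astype(np.int32)

        pos = sim.pos
        d_var = self.depth[:, pos]
        dosage = sim.H.sum(axis=1)  # (S, n)
        alt_true = rng.binomial(d_var, dosage / 2.0)
        ref_true = d_var - alt_true
        e = config.error_rate
        if e > 0:
            r2x = rng.binomial(ref_true, e)
            r2a = rng.binomial(r2x, 1.0 / 3.0)
            a2x = rng.binomial(alt_true, e)
            a2r = rng.binomial(a2x, 1.0 / 3.0)
            self.var_ref_obs = ref_true - r2x + a2r
            self.var_alt_obs = alt_true - a2x + r2a
            self.var_other_obs = (r2x - r2a) + (a2x - a2r)
        else:
            self.var_ref_obs = ref_true
            self.var_alt_obs = alt_true
            self.var_other_obs = np.zeros_like(ref_true)

        if e > 0:
            emat = rng.binomial(self.depth, e)
            emat[:, pos] = 0
            err_sample, err_gpos = np.nonzero(emat)
            self.err_sample = err_sample.astype(np.int32)
            self.err_gpos = err_gpos.astype(np.int64)
            self.err_count = emat[err_sample, err_gpos].astype(np.int32)
            self.err_offset = rng.integers(1, 4, size=err_sample.size, dtype=np.uint8)
        else:
            self.err_sample = np.empty(0, dtype=np.int32)
            self.err_gpos = np.empty(0, dtype=np.int64)
            self.err_count = np.empty(0, dtype=np.int32)
            self.err_offset = np.empty(0, dtype=np.uint8)

        mq_rng = substream(config.seed, "mq")
        mq = np.full(L, 60.0)
        if e > 0:
            mq -= mq_rng.exponential(0.5, size=L)
        for name, start, end in config.contig_bounds():
            for s0, e0 in sim.founders.repeat_mask.intervals(name):
                lo, hi = start + int(s0), start + int(e0)
                mq[lo:hi] -= mq_rng.exponential(10.0, size=hi - lo)
        self.mq = np.round(mq, 4)

        self._ann_cache: dict[int, tuple[float, float, float]] = {}
        self.spiked: dict[int, tuple[int, int, int]] = {}  # gpos -> (alt_code, sample_idx, n_alt)
        self.fragments: list[ReadFragment] = self._make_fragments()

    # -- fragments around planted DNMs --------------------------------------
    def _make_fragments(self) -> list[ReadFragment]:
        config = self.sim.config
        rng = substream(config.seed, "fragments")
        frags: list[ReadFragment] = []
        sample_index = {s: i for i, s in enumerate(self.samples)}
        pos = self.sim.pos
        flen = config.fragment_length
        for d in self.sim.truth.dnms:
            s_idx = sample_index[d.offspring_id]
            gpos = config.global_position(d.contig, d.position - 1)
            col = int(np.searchsorted(pos, gpos))
            n_frag = int(rng.poisson(config.mean_depth_offspring)) \
                if not config.fixed_depth else int(round(config.mean_depth_offspring))
            cname, cstart, cend = next(
                b for b in config.contig_bounds() if b[0] == d.contig
            )
            for i in range(n_frag):
                fstart = gpos - int(rng.integers(0, flen))
                fend = fstart + flen
                hap = int(rng.integers(0, 2))
                i0, i1 = np.searchsorted(pos, [max(fstart, cstart), min(fend, cend)])
                obs = []
                for col_j in range(i0, i1):
                    allele_code = (
                        self.sim.alt[col_j]
                        if self.sim.H[s_idx, hap, col_j]
                        else self.sim.ref[col_j]
                    )
                    if config.error_rate > 0 and rng.random() < config.error_rate:
                        allele_code = (allele_code + rng.integers(1, 4)) % 4
                    contig, local = d.contig, int(pos[col_j]) - cstart
                    obs.append((contig, local + 1, str(BASES[allele_code])))
                if obs:
                    frags.append(
                        ReadFragment(
                            fragment_id=f"{d.offspring_id}:{d.contig}:{d.position}:{i}",
                            observations=tuple(obs),
                        )
                    )
        return frags

    # -- annotation emulation ------------------------------------------------
    def annotations_for(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(BaseQRankSum, ReadPosRankSum, QD) for variant positions.

        Deterministic per position under the master seed. With sequencing
        error the rank sums are standard normal and QD is Normal(18, 3)
        truncated positive; an error-free process has no allele-differential
        biases, so the annotations collapse to their exact central values.
        """
        config = self.sim.config
        if config.error_rate == 0:
            n = len(gpos)
            return np.zeros(n), np.zeros(n), np.full(n, 18.0)
        bq = np.empty(len(gpos))
        rp = np.empty(len(gpos))
        qd = np.empty(len(gpos))
        for i, p in enumerate(np.asarray(gpos).tolist()):
            cached = self._ann_cache.get(p)
            if cached is None:
                r = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed & 0x7FFFFFFF, zlib.crc32(b"annotations") & 0x7FFFFFFF, p]
                    )
                )
                vals = r.standard_normal(3)
                cached = (
                    round(float(vals[0]), 4),
                    round(float(vals[1]), 4),
                    round(max(float(18.0 + 3.0 * vals[2]), 0.1), 4),
                )
                self._ann_cache[p] = cached
            bq[i], rp[i], qd[i] = cached
        return bq, rp, qd

    # -- spike-in interface ---------------------------------------------------
    def depth_of(self, sample: str, contig: str, position: int) -> int:
        s = self.samples.index(sample)
        gpos = self.sim.config.global_position(contig, position - 1)
        return int(self.depth[s, gpos])

    def plant_variant(
        self, sample: str, contig: str, position: int, alt_base: str, n_alt: int
    ) -> None:
        """Convert n_alt reference reads of one sample to ``alt_base``."""
        s = self.samples.index(sample)
        gpos = self.sim.config.global_position(contig, position - 1)
        if gpos in set(self.sim.pos.tolist()):
            raise ValueError(f"{contig}:{position} is not invariant")
        alt_code = int(np.flatnonzero(BASES == alt_base)[0])
        self.spiked[gpos] = (alt_code, s, int(n_alt))


def caller_log_priors(profile: str, target_pi: float) -> np.ndarray:
    """Genotype log-priors for the two emulated callers.

    The primary caller is flat; the secondary weights the heterozygote by
    the population heterozygosity 2*pi — the deliberate difference that
    produces rare low-depth disagreements between the two sources.
    """
    if profile == "primary":
        return np.zeros(3)
    if profile == "secondary":
        h = min(2.0 * target_pi, 0.5)
        h = max(h, 1e-6)
        return np.log([(1.0 - h) / 2.0, h, (1.0 - h) / 2.0])
    raise ValueError(f"unknown caller profile {profile!r}")


def call_from_counts(
    ref_obs: np.ndarray,
    alt_obs: np.ndarray,
    eps_model: float,
    log_priors: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum a-posteriori genotype (0/1/2 alt dosage) and phred GQ from
    ref/alt read counts under a binomial read-sampling model."""
    r = np.asarray(ref_obs, dtype=np.float64)
    a = np.asarray(alt_obs, dtype=np.float64)
    l_ref = np.log1p(-eps_model)
    l_err = np.log(eps_model / 3.0)
    post = np.stack([
        r * l_ref + a * l_err + log_priors[0],
        (r + a) * _LOG_HALF + log_priors[1],
        r * l_err + a * l_ref + log_priors[2],
    ])
    order = np.argsort(post, axis=0)
    gt = order[-1].astype(np.int8)
    best = np.take_along_axis(post, order[-1][None], axis=0)[0]
    second = np.take_along_axis(post, order[-2][None], axis=0)[0]
    gq = np.minimum(np.rint(_PHRED * (best - second)), GQ_CAP).astype(np.int16)
    no_reads = (r + a) == 0
    gt = np.where(no_reads, np.int8(0), gt)
    gq = np.where(no_reads, np.int16(0), gq)
    return gt, gq


def gq_homref(depth: np.ndarray, eps_model: float, log_priors: np.ndarray) -> np.ndarray:
    """Closed-form GQ of a hom-ref call with zero alt reads (vectorised)."""
    d = np.asarray(depth, dtype=np.float64)
    l_ref = np.log1p(-eps_model)
    l_err = np.log(eps_model / 3.0)
    diff_het = d * (l_ref - _LOG_HALF) + (log_priors[0] - log_priors[1])
    diff_hom = d * (l_ref - l_err) + (log_priors[0] - log_priors[2])
    gq = np.minimum(np.rint(_PHRED * np.minimum(diff_het, diff_hom)), GQ_CAP)
    return np.where(d > 0, gq, 0).astype(np.int16)


@dataclass
class CallSet:
    """One emulated caller's genotypes over the variant map.

    ``var_gpos`` covers the simulator's variant map plus any invariant
    position promoted to a variant record (error reads or spike-ins).
    ``has_alt`` marks positions this caller would emit with an ALT allele.
    Sparse GQ overrides cover invariant positions carrying error reads.
    """

    profile: str
    pileups: PileupSet
    eps_model: float
    log_priors: np.ndarray
    var_gpos: np.ndarray
    var_ref: np.ndarray  # uint8 codes
    var_alt: np.ndarray
    GT: np.ndarray  # (S, n) int8; -1 missing
    GQ: np.ndarray  # (S, n) int16
    AD_ref: np.ndarray
    AD_alt: np.ndarray
    AD_other: np.ndarray
    bq: np.ndarray
    rp: np.ndarray
    qd: np.ndarray
    mq_var: np.ndarray
    has_alt: np.ndarray
    err_gpos: np.ndarray
    err_sample: np.ndarray
    err_gq: np.ndarray

    @property
    def samples(self) -> list[str]:
        return self.pileups.samples

    def column_of(self, gpos: int) -> int | None:
        i = int(np.searchsorted(self.var_gpos, gpos))
        if i < len(self.var_gpos) and self.var_gpos[i] == gpos:
            return i
        return None


def call_genotypes(pileups: PileupSet, profile: str = "primary") -> CallSet:
    """Emulated genotype caller over a pileup set.

    Maximum-likelihood genotype per sample per site under a binomial read
    model with an error floor; GQ is the phred-scaled margin over the
    second-best genotype, capped at 99. Invariant positions whose error (or
    spiked) reads win a non-reference call are promoted to variant records.
    """
    sim = pileups.sim
    config = sim.config
    eps = max(config.error_rate, MIN_CALLER_ERROR)
    lp = caller_log_priors(profile, config.target_pi)
    S = len(pileups.samples)

    # error-read calls at invariant positions (sparse)
    if pileups.err_gpos.size:
        e_depth = pileups.depth[pileups.err_sample, pileups.err_gpos]
        e_gt, e_gq = call_from_counts(
            e_depth - pileups.err_count, pileups.err_count, eps, lp
        )
    else:
        e_gt = np.empty(0, dtype=np.int8)
        e_gq = np.empty(0, dtype=np.int16)

    seq = sim.sequence_codes()
    promoted: dict[int, tuple[int, int]] = {}  # gpos -> (alt_code, err_row_of_max)
    for row in np.flatnonzero(e_gt > 0).tolist():
        gpos = int(pileups.err_gpos[row])
        alt_code = int((seq[gpos] + pileups.err_offset[row]) % 4)
        prev = promoted.get(gpos)
        if prev is None or pileups.err_count[row] > pileups.err_count[prev[1]]:
            promoted[gpos] = (alt_code, row)
    for gpos, (alt_code, s_idx, n_alt) in pileups.spiked.items():
        promoted.setdefault(gpos, (alt_code, -1))

    extra_gpos = np.array(sorted(promoted), dtype=np.int64)
    all_gpos = np.concatenate([sim.pos, extra_gpos])
    order = np.argsort(all_gpos, kind="stable")
    all_gpos = all_gpos[order]
    n_all = all_gpos.size

    ref = np.concatenate([sim.ref, seq[extra_gpos]])[order]
    alt_extra = np.array([promoted[int(p)][0] for p in extra_gpos], dtype=np.uint8)
    alt = np.concatenate([sim.alt, alt_extra])[order]

    AD_ref = np.zeros((S, n_all), dtype=np.int32)
    AD_alt = np.zeros((S, n_all), dtype=np.int32)
    AD_other = np.zeros((S, n_all), dtype=np.int32)
    sim_cols = np.searchsorted(all_gpos, sim.pos)
    AD_ref[:, sim_cols] = pileups.var_ref_obs
    AD_alt[:, sim_cols] = pileups.var_alt_obs
    AD_other[:, sim_cols] = pileups.var_other_obs
    # promoted columns: depth minus error/spike reads is reference
    extra_cols = np.searchsorted(all_gpos, extra_gpos)
    if extra_gpos.size:
        AD_ref[:, extra_cols] = pileups.depth[:, extra_gpos]
        err_at = {}
        for row in range(pileups.err_gpos.size):
            gpos = int(pileups.err_gpos[row])
            if gpos in promoted:
                err_at.setdefault(gpos, []).append(row)
        col_of = {int(p): int(c) for p, c in zip(extra_gpos, extra_cols)}
        for gpos, rows in err_at.items():
            alt_code = promoted[gpos][0]
            col = col_of[gpos]
            for row in rows:
                s = int(pileups.err_sample[row])
                cnt = int(pileups.err_count[row])
                base = int((seq[gpos] + pileups.err_offset[row]) % 4)
                AD_ref[s, col] -= cnt
                if base == alt_code:
                    AD_alt[s, col] += cnt
                else:
                    AD_other[s, col] += cnt
        for gpos, (alt_code, s_idx, n_alt) in pileups.spiked.items():
            col = col_of[gpos]
            take = min(n_alt, int(AD_ref[s_idx, col]))
            AD_ref[s_idx, col] -= take
            AD_alt[s_idx, col] += take

    GT, GQ = call_from_counts(AD_ref, AD_alt, eps, lp)
    depth_all = pileups.depth[:, all_gpos]
    missing = depth_all == 0
    GT = GT.astype(np.int8)
    GT[missing] = -1
    GQ[missing] = 0

    bq, rp, qd = pileups.annotations_for(all_gpos)
    return CallSet(
        profile=profile,
        pileups=pileups,
        eps_model=eps,
        log_priors=lp,
        var_gpos=all_gpos,
        var_ref=ref,
        var_alt=alt,
        GT=GT,
        GQ=GQ,
        AD_ref=AD_ref,
        AD_alt=AD_alt,
        AD_other=AD_other,
        bq=bq,
        rp=rp,
        qd=qd,
        mq_var=pileups.mq[all_gpos],
        has_alt=(GT > 0).any(axis=0),
        err_gpos=pileups.err_gpos,
        err_sample=pileups.err_sample,
        err_gq=e_gq,
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _vcf_sample_field(gt_code: int, ad: str, dp: int, gq: int) -> str:
    if gt_code < 0:
        return f"./.:{ad}:{dp}:."
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[gt_code]
    return f"{gt}:{ad}:{dp}:{gq}"


def _write_vcf_from_calls(
    path: Path,
    calls: CallSet,
    variant_positions: np.ndarray,
    all_sites: bool,
) -> None:
    sim = calls.pileups.sim
    config = sim.config
    seq = sim.sequence_codes()
    samples = calls.samples
    S = len(samples)
    var_set_cols = {int(p): int(i) for i, p in enumerate(calls.var_gpos)}
    variant_set = set(int(p) for p in variant_positions)
    gq0 = {
        s: gq_homref(calls.pileups.depth[s], calls.eps_model, calls.log_priors)
        for s in range(S)
    }
    err_override: dict[tuple[int, int], int] = {}
    for row in range(calls.err_gpos.size):
        err_override[(int(calls.err_sample[row]), int(calls.err_gpos[row]))] = int(
            calls.err_gq[row]
        )
    err_count_at: dict[tuple[int, int], int] = {}
    for row in range(calls.err_gpos.size):
        err_count_at[(int(calls.err_sample[row]), int(calls.err_gpos[row]))] = int(
            calls.pileups.err_count[row]
        )

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=dnmpipe-simulator-{calls.profile}\n")
        for name, length in config.contig_lengths().items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">\n')
        fh.write('##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="Base quality rank sum">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")

        for name, cstart, cend in config.contig_bounds():
            if all_sites:
                span = range(cstart, cend)
            else:
                span = [p for p in sorted(variant_set) if cstart <= p < cend]
            for gpos in span:
                local1 = gpos - cstart + 1
                refb = str(BASES[seq[gpos]])
                if gpos in variant_set:
                    col = var_set_cols[gpos]
                    altb = str(BASES[calls.var_alt[col]])
                    info = (
                        f"MQ={calls.mq_var[col]:.6g};QD={calls.qd[col]:.6g};"
                        f"BaseQRankSum={calls.bq[col]:.6g};"
                        f"ReadPosRankSum={calls.rp[col]:.6g}"
                    )
                    fields = []
                    for s in range(S):
                        dp = int(calls.pileups.depth[s, gpos])
                        ad = f"{calls.AD_ref[s, col]},{calls.AD_alt[s, col]}"
                        fields.append(
                            _vcf_sample_field(
                                int(calls.GT[s, col]), ad, dp, int(calls.GQ[s, col])
                            )
                        )
                    fh.write(
                        f"{name}\t{local1}\t.\t{refb}\t{altb}\t.\tPASS\t{info}\t"
                        "GT:AD:DP:GQ\t" + "\t".join(fields) + "\n"
                    )
                else:
                    info = f"MQ={calls.pileups.mq[gpos]:.6g}"
                    fields = []
                    for s in range(S):
                        dp = int(calls.pileups.depth[s, gpos])
                        col = var_set_cols.get(gpos)
                        if col is not None:
                            gt_code = int(calls.GT[s, col])
                            gq = int(calls.GQ[s, col])
                            ad = str(int(calls.AD_ref[s, col]))
                        else:
                            gq = err_override.get(
                                (s, gpos), int(gq0[s][gpos])
                            )
                            gt_code = 0 if dp > 0 else -1
                            ad = str(dp - err_count_at.get((s, gpos), 0))
                        fields.append(_vcf_sample_field(gt_code, ad, dp, gq))
                    fh.write(
                        f"{name}\t{local1}\t.\t{refb}\t.\t.\tPASS\t{info}\t"
                        "GT:AD:DP:GQ\t" + "\t".join(fields) + "\n"
                    )


def emit(
    sim: PedigreeSim,
    pileups: PileupSet,
    calls_primary: CallSet,
    calls_secondary: CallSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulated study to disk.

    Produces the primary all-sites VCF, a secondary VCF restricted to
    positions with a non-reference call in either caller, repeat and
    low-mappability BEDs, the phasing fragments TSV, the truth TSV, the
    pedigree TSV and a config snapshot. Re-running with the same seed
    reproduces every file byte for byte. Intended for modest genome sizes
    (the all-sites VCF has one row per base).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = sim.config
    paths = {
        "primary_vcf": out / "primary.vcf",
        "secondary_vcf": out / "secondary.vcf",
        "repeats_bed": out / "repeats.bed",
        "mappability_bed": out / "low_mappability.bed",
        "fragments_tsv": out / "fragments.tsv",
        "truth_tsv": out / "truth.tsv",
        "pedigree_tsv": out / "pedigree.tsv",
        "config_yaml": out / "config.yaml",
    }

    primary_variants = calls_primary.var_gpos[calls_primary.has_alt]
    _write_vcf_from_calls(paths["primary_vcf"], calls_primary, primary_variants, all_sites=True)
    union = np.union1d(primary_variants, calls_secondary.var_gpos[calls_secondary.has_alt])
    secondary_variants = calls_secondary.var_gpos[
        np.isin(calls_secondary.var_gpos, union) & calls_secondary.has_alt
    ]
    _write_vcf_from_calls(paths["secondary_vcf"], calls_secondary, secondary_variants,
                          all_sites=False)
    # positions only the primary caller considers variant still need secondary
    # genotypes for concordance checks: append them as invariant-style rows
    only_primary = np.setdiff1d(primary_variants, secondary_variants)
    if only_primary.size:
        _append_secondary_rows(paths["secondary_vcf"], calls_secondary, only_primary)

    sim.founders.repeat_mask.to_bed(paths["repeats_bed"])
    _mappability_bed(sim, paths["mappability_bed"])

    with open(paths["fragments_tsv"], "w") as fh:
        fh.write("fragment_id\tcontig\tposition\tallele\n")
        for frag in pileups.fragments:
            for contig, pos1, allele in frag.observations:
                fh.write(f"{frag.fragment_id}\t{contig}\t{pos1}\t{allele}\n")

    sim.truth.to_tsv(paths["truth_tsv"])
    write_pedigree(sim.pedigree, paths["pedigree_tsv"])
    config.to_yaml(paths["config_yaml"])
    return paths


def _append_secondary_rows(path: Path, calls: CallSet, gpos_list: np.ndarray) -> None:
    """Rows for loci the secondary caller saw as invariant (hom-ref calls),
    merged into coordinate order."""
    sim = calls.pileups.sim
    config = sim.config
    seq = sim.sequence_codes()
    S = len(calls.samples)
    col_of = {int(p): int(i) for i, p in enumerate(calls.var_gpos)}
    gq0 = {
        s: gq_homref(calls.pileups.depth[s], calls.eps_model, calls.log_priors)
        for s in range(S)
    }
    rows = []
    for gpos in gpos_list.tolist():
        contig, local = config.locus(int(gpos))
        refb = str(BASES[seq[gpos]])
        fields = []
        col = col_of.get(int(gpos))
        for s in range(S):
            dp = int(calls.pileups.depth[s, gpos])
            if col is not None:
                fields.append(
                    _vcf_sample_field(
                        int(calls.GT[s, col]),
                        f"{calls.AD_ref[s, col]},{calls.AD_alt[s, col]}",
                        dp,
                        int(calls.GQ[s, col]),
                    )
                )
            else:
                gt_code = 0 if dp > 0 else -1
                fields.append(_vcf_sample_field(gt_code, str(dp), dp, int(gq0[s][gpos])))
        info = f"MQ={calls.pileups.mq[gpos]:.6g}"
        alt = str(BASES[calls.var_alt[col]]) if col is not None else "."
        rows.append(
            (contig, local + 1,
             f"{contig}\t{local + 1}\t.\t{refb}\t{alt}\t.\tPASS\t{info}\t"
             "GT:AD:DP:GQ\t" + "\t".join(fields))
        )
    # merge with existing body in coordinate order
    with open(path) as fh:
        lines = fh.readlines()
    header = [l for l in lines if l.startswith("#")]
    body = [l.rstrip("\n") for l in lines if not l.startswith("#")]
    order_of = {name: i for i, (name, _, _) in enumerate(config.contig_bounds())}

    def sort_key(line: str) -> tuple[int, int]:
        parts = line.split("\t", 2)
        return (order_of[parts[0]], int(parts[1]))

    body.extend(r[2] for r in rows)
    body.sort(key=sort_key)
    with open(path, "w") as fh:
        fh.writelines(header)
        fh.write("\n".join(body) + "\n")


def _mappability_bed(sim: PedigreeSim, path: Path) -> None:
    """Exact-match k-mer mappability over the simulated sequence; positions
    scoring below 1 become the low-mappability mask."""
    config = sim.config
    seq = sim.sequence_codes()
    pairs: list[tuple[str, int, int]] = []
    k = min(config.mappability_k, config.genome_length)
    for name, start, end in config.contig_bounds():
        if end - start < k:
            continue
        text = "".join(BASES[seq[start:end]])
        scores = kmer_mappability(text, k, 0)
        iset = low_mappability_intervals(scores, name)
        for s, e in iset.intervals(name):
            pairs.append((name, int(s), int(e)))
    IntervalSet.from_pairs(pairs).to_bed(path)
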