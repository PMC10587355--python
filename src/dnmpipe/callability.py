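"""Callable-genome filtering.

The filter chain mirrors a trio sequencing study design: genomic masks
(repeats + low mappability) are excluded, empirical quality thresholds are
derived as 5th/95th percentiles of the annotation distributions at
high-confidence heterozygous sites (sites where the parents are opposite
homozygotes and every offspring is heterozygous), and a site is "callable"
for a trio when it passes the site-level annotation filters and all three
trio members have confident genotypes with depth inside their per-sample
band. Mapping quality and quality-by-depth are filtered with the lower
cut-off only, so unusually good sites are not penalised; the two rank-sum
annotations are filtered two-sided. Missing annotations pass (the statistic
is undefined at sites without variant reads; absence is not evidence of low
quality).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .pedigree_data import (
    BIALLELIC_SNP,
    MONOMORPHIC,
    GenotypeCall,
    IntervalSet,
    Pedigree,
    SiteRecord,
    minor_allele_balance,
)

__all__ = [
    "ThresholdSet",
    "build_exclusion_mask",
    "kmer_mappability",
    "low_mappability_intervals",
    "masked_fraction",
    "find_high_confidence_hets",
    "derive_thresholds",
    "classify_callable",
    "count_callable",
]


@dataclass
class ThresholdSet:
    """Empirical filter cut-offs derived from high-confidence het sites.

    Two-sided bounds for the rank-sum annotations, lower bounds only for MQ
    and QD, and a per-sample (low, high) depth band.
    """

    base_quality_rank_sum: tuple[float, float]
    read_position_rank_sum: tuple[float, float]
    mapping_quality_low: float
    quality_by_depth_low: float
    depth: dict[str, tuple[float, float]]
    n_sites: int = 0

    def __post_init__(self) -> None:
        for name in ("base_quality_rank_sum", "read_position_rank_sum"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low bound {lo} exceeds high bound {hi}")
        for sample, (lo, hi) in self.depth.items():
            if lo > hi:
                raise ValueError(f"depth bounds for {sample}: low {lo} > high {hi}")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "base_quality_rank_sum": [float(x) for x in self.base_quality_rank_sum],
            "read_position_rank_sum": [float(x) for x in self.read_position_rank_sum],
            "mapping_quality_low": float(self.mapping_quality_low),
            "quality_by_depth_low": float(self.quality_by_depth_low),
            "depth": {s: [float(lo), float(hi)] for s, (lo, hi) in self.depth.items()},
            "n_sites": int(self.n_sites),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            base_quality_rank_sum=tuple(d["base_quality_rank_sum"]),
            read_position_rank_sum=tuple(d["read_position_rank_sum"]),
            mapping_quality_low=d["mapping_quality_low"],
            quality_by_depth_low=d["quality_by_depth_low"],
            depth={s: tuple(v) for s, v in d["depth"].items()},
            n_sites=d.get("n_sites", 0),
        )


def build_exclusion_mask(repeats: IntervalSet, low_mappability: IntervalSet) -> IntervalSet:
    """Union of the repeat and low-mappability masks (merged)."""
    return repeats.union(low_mappability)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_mappability(sequence: str, k: int, max_mismatches: int = 0) -> np.ndarray:
    """Per-k-mer-start mappability score in (0, 1].

    Score at position i is 1 / (number of positions j whose k-mer is within
    ``max_mismatches`` Hamming distance of the k-mer at i), including i
    itself. Exact matching (max_mismatches=0) is counted with a hash table
    and scales to whole synthetic genomes; the mismatch-tolerant path is a
    brute-force pairwise Hamming scan intended for sequences up to a few kb.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(sequence) - k + 1
    if max_mismatches >= k:
        # every k-mer within distance of every other: saturation limit
        return np.full(n, 1.0 / n)
    if max_mismatches == 0:
        counts: dict[str, int] = {}
        for i in range(n):
            kmer = sequence[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        return np.array([1.0 / counts[sequence[i : i + k]] for i in range(n)])
    codes = np.array([_CODE[b] for b in sequence], dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    counts = np.zeros(n, dtype=np.int64)
    chunk = max(1, int(2e7) // (n * k))
    for start in range(0, n, chunk):
        block = windows[start : start + chunk]  # (c, k)
        dist = (block[:, None, :] != windows[None, :, :]).sum(axis=2)
        counts[start : start + chunk] = (dist <= max_mismatches).sum(axis=1)
    return 1.0 / counts


def low_mappability_intervals(scores: np.ndarray, contig: str) -> IntervalSet:
    """Positions with mappability score < 1 (strict), as merged intervals."""
    low = np.flatnonzero(scores < 1.0)
    if low.size == 0:
        return IntervalSet()
    breaks = np.flatnonzero(np.diff(low) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [low.size - 1]))
    pairs = [(contig, int(low[s]), int(low[e]) + 1) for s, e in zip(starts, ends)]
    return IntervalSet.from_pairs(pairs)


def masked_fraction(masked_bases: int, assembly_length: int) -> float:
    """Percent of the assembly covered by a mask, to two decimals."""
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    if not 0 <= masked_bases <= assembly_length:
        raise ValueError("masked_bases must lie in [0, assembly_length]")
    return round(100.0 * masked_bases / assembly_length, 2)


def _confident_hom(call: GenotypeCall, min_gq: float, hom_ab_max: float) -> bool:
    if call.is_missing or call.gq is None or call.gq < min_gq or not call.is_hom:
        return False
    ab = minor_allele_balance(call)
    return ab is not None and ab < hom_ab_max


def _confident_het(call: GenotypeCall, min_gq: float, het_ab_min: float) -> bool:
    if call.is_missing or call.gq is None or call.gq < min_gq or not call.is_het:
        return False
    ab = minor_allele_balance(call)
    return ab is not None and ab >= het_ab_min


def find_high_confidence_hets(
    sites: Iterable[SiteRecord],
    pedigree: Pedigree,
    mask: IntervalSet,
    min_gq: float = 20.0,
    hom_ab_max: float = 0.1,
    het_ab_min: float = 0.25,
) -> list[SiteRecord]:
    """Biallelic SNPs where the parents are opposite homozygotes and every
    offspring is heterozygous, with confident calls all around.

    Parents count as homozygous at minor allele balance < ``hom_ab_max``;
    offspring as heterozygous at minor allele balance >= ``het_ab_min``.
    """
    out: list[SiteRecord] = []
    for site in sites:
        if site.site_class != BIALLELIC_SNP:
            continue
        if mask.contains(site.contig, site.position - 1):
            continue
        calls = site.calls
        if any(s not in calls or calls[s].is_missing for s in pedigree.samples):
            continue
        mother = calls[pedigree.mother_id]
        father = calls[pedigree.father_id]
        if not (_confident_hom(mother, min_gq, hom_ab_max)
                and _confident_hom(father, min_gq, hom_ab_max)):
            continue
        if mother.alleles[0] == father.alleles[0]:
            continue  # parents must be homozygous for *different* alleles
        if all(_confident_het(calls[o], min_gq, het_ab_min) for o in pedigree.offspring_ids):
            out.append(site)
    return out


def derive_thresholds(
    hc_sites: Sequence[SiteRecord],
    pedigree: Pedigree,
    percentile_low: float = 5.0,
    percentile_high: float = 95.0,
    min_sites: int = 100,
) -> ThresholdSet:
    """5th/95th-percentile cut-offs from the high-confidence het sites.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default). MQ and QD store the lower bound only.
    """
    if len(hc_sites) < min_sites:
        raise ValueError(
            f"only {len(hc_sites)} high-confidence het sites; need at least {min_sites}"
        )

    def _pct(values: list[float], both: bool) -> tuple[float, float] | float:
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("annotation absent from every high-confidence site")
        if both:
            lo, hi = np.percentile(arr, [percentile_low, percentile_high])
            return float(lo), float(hi)
        return float(np.percentile(arr, percentile_low))

    bq = [s.base_quality_rank_sum for s in hc_sites if s.base_quality_rank_sum is not None]
    rp = [s.read_position_rank_sum for s in hc_sites if s.read_position_rank_sum is not None]
    mq = [s.mapping_quality for s in hc_sites if s.mapping_quality is not None]
    qd = [s.quality_by_depth for s in hc_sites if s.quality_by_depth is not None]

    depth: dict[str, tuple[float, float]] = {}
    for sample in pedigree.samples:
        depths = [
            s.calls[sample].total_depth
            for s in hc_sites
            if s.calls[sample].total_depth is not None
        ]
        depth[sample] = _pct(depths, both=True)

    return ThresholdSet(
        base_quality_rank_sum=_pct(bq, both=True),
        read_position_rank_sum=_pct(rp, both=True),
        mapping_quality_low=_pct(mq, both=False),
        quality_by_depth_low=_pct(qd, both=False),
        depth=depth,
        n_sites=len(hc_sites),
    )


def site_filters_pass(site: SiteRecord, thresholds: ThresholdSet) -> bool:
    """Site-level annotation filters; a missing annotation passes."""
    bq_lo, bq_hi = thresholds.base_quality_rank_sum
    rp_lo, rp_hi = thresholds.read_position_rank_sum
    if site.base_quality_rank_sum is not None and not (
        bq_lo <= site.base_quality_rank_sum <= bq_hi
    ):
        return False
    if site.read_position_rank_sum is not None and not (
        rp_lo <= site.read_position_rank_sum <= rp_hi
    ):
        return False
    if site.mapping_quality is not None and site.mapping_quality < thresholds.mapping_quality_low:
        return False
    if site.quality_by_depth is not None and site.quality_by_depth < thresholds.quality_by_depth_low:
        return False
    return True


def classify_callable(
    site: SiteRecord,
    trio: tuple[str, str, str],
    thresholds: ThresholdSet,
    mask: IntervalSet,
    min_gq: float = 20.0,
) -> bool:
    """True iff the site is confidently callable for one (mother, father,
    offspring) trio: monomorphic or biallelic SNP, outside the mask, passing
    the annotation filters, with all three members called at GQ >= min_gq
    and depth inside their per-sample band."""
    if site.site_class not in (MONOMORPHIC, BIALLELIC_SNP):
        return False
    if mask.contains(site.contig, site.position - 1):
        return False
    if not site_filters_pass(site, thresholds):
        return False
    for sample in trio:
        call = site.calls.get(sample)
        if call is None or call.is_missing:
            return False
        if call.gq is None or call.gq < min_gq:
            return False
        if call.total_depth is None:
            return False
        lo, hi = thresholds.depth[sample]
        if not (lo <= call.total_depth <= hi):
            return False
    return True


def count_callable(
    sites: Iterable[SiteRecord],
    pedigree: Pedigree,
    thresholds: ThresholdSet,
    mask: IntervalSet,
    min_gq: float = 20.0,
) -> tuple[dict[str, int], int]:
    """Per-trio callable-site counts and their pedigree total S.

    A genomic site contributes once per trio in which it is callable, so the
    total S is the sum of the per-trio counts — the denominator convention
    of the per-generation rate m / (2S).
    """
    counts = {o: 0 for o in pedigree.offspring_ids}
    trios = pedigree.trios()
    for site in sites:
        for mother, father, offspring in trios:
            if classify_callable(site, (mother, father, offspring), thresholds, mask, min_gq):
                counts[offspring] += 1
    return counts, sum(counts.values())
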