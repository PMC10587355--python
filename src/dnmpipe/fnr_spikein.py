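"""Spike-in estimation of the pipeline false negative rate.

Synthetic mutations are planted at invariant, callable sites in a single
offspring's read pileups, with variant allele fractions resampled from the
observed allele-balance distribution at high-confidence heterozygous sites.
Detection is re-run with the original thresholds; FNR = missed / planted.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dnm_calling import CandidateDNM
from .pedigree_data import SiteRecord

__all__ = [
    "SpikeSite",
    "SpikePlan",
    "empirical_vaf_distribution",
    "make_spike_plan",
    "apply_spikes",
    "estimate_fnr",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SpikeSite:
    contig: str
    position: int  # 1-based
    target_sample: str
    target_vaf: float
    planted_alt: str


@dataclass
class SpikePlan:
    """Planted-mutation plan: unique invariant callable positions, each with
    a target VAF and a planted alt base."""

    sites: list[SpikeSite]
    seed: int

    def __post_init__(self) -> None:
        keys = [(s.contig, s.position) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("spike plan positions must be unique")
        for s in self.sites:
            if not 0.0 < s.target_vaf <= 1.0:
                raise ValueError(f"target VAF {s.target_vaf} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.sites)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["contig", "position", "target_sample", "target_vaf", "planted_alt"])
            for s in self.sites:
                w.writerow([s.contig, s.position, s.target_sample,
                            format(s.target_vaf, ".8g"), s.planted_alt])

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "SpikePlan":
        sites = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                sites.append(SpikeSite(
                    contig=row["contig"],
                    position=int(row["position"]),
                    target_sample=row["target_sample"],
                    target_vaf=float(row["target_vaf"]),
                    planted_alt=row["planted_alt"],
                ))
        return cls(sites=sites, seed=seed)


def empirical_vaf_distribution(
    hc_sites: Sequence[SiteRecord], offspring_id: str
) -> np.ndarray:
    """Alt-allele read fractions for one sample at the high-confidence het
    sites — the multiset a spike plan resamples from (with replacement,
    under an explicit seed)."""
    vafs: list[float] = []
    for site in hc_sites:
        call = site.calls.get(offspring_id)
        if call is None or call.allele_depths is None:
            continue
        depths = call.allele_depths[:2]
        total = sum(depths)
        if len(depths) < 2 or total == 0:
            continue
        vafs.append(depths[1] / total)
    if not vafs:
        raise ValueError(f"no heterozygous allele balances available for {offspring_id}")
    return np.asarray(vafs)


def make_spike_plan(
    invariant_callable_sites: Sequence[tuple[str, int, str]],
    n: int,
    vaf_source: np.ndarray,
    offspring_id: str,
    seed: int,
) -> SpikePlan:
    """Sample n distinct sites uniformly without replacement and assign each
    a resampled VAF and a planted alt drawn uniformly from the three
    non-reference bases.

    ``invariant_callable_sites`` is a sequence of (contig, 1-based position,
    ref_base) triples, already restricted to invariant callable positions.
    """
    if n > len(invariant_callable_sites):
        raise ValueError(
            f"requested {n} spike sites but only {len(invariant_callable_sites)} eligible"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(invariant_callable_sites), size=n, replace=False)
    vafs = rng.choice(np.asarray(vaf_source), size=n, replace=True)
    sites = []
    for i, k in enumerate(chosen):
        contig, pos, ref = invariant_callable_sites[int(k)]
        others = [b for b in _BASES if b != ref]
        alt = others[int(rng.integers(0, 3))]
        sites.append(SpikeSite(contig, pos, offspring_id, float(vafs[i]), alt))
    return SpikePlan(sites=sites, seed=seed)


def apply_spikes(pileups, plan: SpikePlan) -> list[dict]:
    """Plant the plan into a pileup set, in place, and return the truth
    records.

    At each plan site, round(VAF x depth) reference reads of the target
    sample are converted to the planted alt; every other sample is left
    untouched. A site where the target sample has zero depth is recorded as
    planted-but-uncoverable (converted = 0, covered = False).

    ``pileups`` is any object with the pileup interface of
    :class:`dnmpipe.synthetic.PileupSet` (``depth_of`` and
    ``plant_variant``).
    """
    truth: list[dict] = []
    for s in plan.sites:
        depth = pileups.depth_of(s.target_sample, s.contig, s.position)
        n_alt = int(np.round(s.target_vaf * depth))
        covered = depth > 0
        if covered:
            pileups.plant_variant(s.target_sample, s.contig, s.position, s.planted_alt, n_alt)
        truth.append({
            "contig": s.contig,
            "position": s.position,
            "target_sample": s.target_sample,
            "target_vaf": s.target_vaf,
            "planted_alt": s.planted_alt,
            "n_alt_reads": n_alt,
            "covered": covered,
        })
    return truth


def estimate_fnr(
    truth_table: Sequence[dict],
    detected_candidates: Iterable[CandidateDNM],
) -> dict:
    """FNR = (planted - detected) / planted.

    A planted site counts as detected iff a concordant candidate was emitted
    at that site for the target sample.
    """
    n_planted = len(truth_table)
    if n_planted == 0:
        raise ValueError("no planted sites; FNR undefined")
    detected_keys = {
        (c.contig, c.position, c.offspring_id)
        for c in detected_candidates
        if c.concordance_status == "concordant"
    }
    n_detected = sum(
        1 for t in truth_table
        if (t["contig"], t["position"], t["target_sample"]) in detected_keys
    )
    return {
        "n_planted": n_planted,
        "n_detected": n_detected,
        "fnr": (n_planted - n_detected) / n_planted,
    }
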