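"""Mendelian-violation de novo mutation calling.

Candidates are sites, callable for a focal trio, where both parents are
confidently homozygous for the same allele and the focal offspring is
heterozygous for an allele absent from both parents. Candidates are
confirmed by concordance with an independent secondary genotype source and
optionally annotated with wet-lab validation outcomes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .callability import ThresholdSet, classify_callable
from .pedigree_data import (
    BIALLELIC_SNP,
    GenotypeCall,
    IntervalSet,
    Pedigree,
    SiteRecord,
    minor_allele_balance,
)

__all__ = [
    "CandidateDNM",
    "find_candidates",
    "concordance_confirm",
    "classify_substitution",
    "mendelian_consistency",
    "summarize_validation",
]

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine, else
    'transversion'. Identical bases are fatal."""
    if ref_base == alt_base:
        raise ValueError(f"substitution requires two distinct bases, got {ref_base!r} twice")
    pair = {ref_base, alt_base}
    if not pair <= {"A", "C", "G", "T"}:
        raise ValueError(f"non-nucleotide bases: {ref_base!r}, {alt_base!r}")
    return "transition" if pair in _TRANSITIONS else "transversion"


@dataclass
class CandidateDNM:
    """A Mendelian-violation candidate for one (site, offspring) pair."""

    contig: str
    position: int  # 1-based
    offspring_id: str
    parental_allele: str
    mutant_allele: str
    offspring_allele_balance: float
    substitution_class: str
    concordance_status: str = "unchecked"  # concordant | discordant after confirmation
    validation_status: str = "untested"  # confirmed | refuted | unvalidated | untested
    parental_origin: str = "undetermined"  # maternal | paternal | undetermined
    clustered: bool = False  # another offspring shares the variant at this site
    genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parental_allele == self.mutant_allele:
            raise ValueError("parental and mutant alleles must differ")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.offspring_id)


def find_candidates(
    sites: Iterable[SiteRecord],
    pedigree: Pedigree,
    thresholds: ThresholdSet,
    mask: IntervalSet,
    min_mutant_ab: float = 0.25,
    hom_ab_max: float = 0.1,
    min_gq: float = 20.0,
    require_zero_parent_alt: bool = False,
) -> list[CandidateDNM]:
    """Screen callable sites for Mendelian violations, one candidate per
    (site, offspring).

    Parental homozygosity uses the same minor-allele-balance < ``hom_ab_max``
    rule as high-confidence het extraction; the offspring must be
    heterozygous with the novel allele supported by at least
    ``min_mutant_ab`` of its reads. ``require_zero_parent_alt`` additionally
    demands zero mutant-allele reads in either parent (off by default).
    Candidates sharing a site across offspring are flagged ``clustered``
    (likely an undercalled inherited variant).
    """
    out: list[CandidateDNM] = []
    for site in sites:
        if site.site_class != BIALLELIC_SNP:
            continue
        mother = site.calls.get(pedigree.mother_id)
        father = site.calls.get(pedigree.father_id)
        if mother is None or father is None or mother.is_missing or father.is_missing:
            continue
        if not (mother.is_hom and father.is_hom and mother.alleles == father.alleles):
            continue
        for hom in (mother, father):
            if hom.gq is None or hom.gq < min_gq:
                mother = None
                break
            ab = minor_allele_balance(hom)
            if ab is None or ab >= hom_ab_max:
                mother = None
                break
        if mother is None:
            continue
        parental = site.calls[pedigree.mother_id].alleles[0]
        mutant = next(a for a in site.alleles if a != parental)
        if require_zero_parent_alt:
            mut_idx = site.alleles.index(mutant)
            skip = False
            for pid in (pedigree.mother_id, pedigree.father_id):
                ad = site.calls[pid].allele_depths
                if ad is not None and len(ad) > mut_idx and ad[mut_idx] > 0:
                    skip = True
            if skip:
                continue
        site_candidates: list[CandidateDNM] = []
        for _, _, offspring in pedigree.trios():
            call = site.calls.get(offspring)
            if call is None or call.is_missing or not call.is_het:
                continue
            if mutant not in call.alleles:
                continue
            ab = minor_allele_balance(call)
            if ab is None or ab < min_mutant_ab:
                continue
            if not classify_callable(
                site, (pedigree.mother_id, pedigree.father_id, offspring),
                thresholds, mask, min_gq,
            ):
                continue
            site_candidates.append(
                CandidateDNM(
                    contig=site.contig,
                    position=site.position,
                    offspring_id=offspring,
                    parental_allele=parental,
                    mutant_allele=mutant,
                    offspring_allele_balance=ab,
                    substitution_class=classify_substitution(parental, mutant),
                    genotypes={
                        pedigree.mother_id: site.calls[pedigree.mother_id].alleles,
                        pedigree.father_id: site.calls[pedigree.father_id].alleles,
                        offspring: call.alleles,
                    },
                )
            )
        if len(site_candidates) > 1:
            for c in site_candidates:
                c.clustered = True
        out.extend(site_candidates)
    return out


def _unordered(alleles: tuple[str, str] | None) -> frozenset | None:
    if alleles is None:
        return None
    return frozenset((alleles[0], alleles[1])) if alleles[0] != alleles[1] else frozenset(
        (alleles[0],)
    )


def concordance_confirm(
    candidates: Sequence[CandidateDNM],
    secondary_genotypes: Mapping[tuple[str, int], SiteRecord],
) -> list[CandidateDNM]:
    """Set concordance_status by comparing trio genotypes against an
    independent genotype source at each candidate locus.

    Concordant iff the unordered allele pairs of mother, father and focal
    offspring match between the two sources. A locus absent from the
    secondary source is discordant (with a warning). Only concordant
    candidates proceed to rate estimation.
    """
    confirmed: list[CandidateDNM] = []
    for cand in candidates:
        rec = secondary_genotypes.get((cand.contig, cand.position))
        if rec is None:
            warnings.warn(
                f"candidate locus {cand.contig}:{cand.position} absent from secondary "
                "genotype source; marking discordant"
            )
            confirmed.append(replace(cand, concordance_status="discordant"))
            continue
        ok = True
        for sample, primary_alleles in cand.genotypes.items():
            sec = rec.calls.get(sample)
            if sec is None or _unordered(sec.alleles) != _unordered(primary_alleles):
                ok = False
                break
        confirmed.append(
            replace(cand, concordance_status="concordant" if ok else "discordant")
        )
    return confirmed


def mendelian_consistency(
    sites: Iterable[SiteRecord],
    trio: tuple[str, str, str],
    min_gq: float = 20.0,
    hom_ab_max: float = 0.1,
    het_ab_min: float = 0.25,
) -> float | None:
    """Fraction of informative sites consistent with Mendelian transmission.

    A site is informative when all three trio members have confident calls
    (GQ >= min_gq; homozygotes at minor AB < hom_ab_max, heterozygotes at
    minor AB >= het_ab_min) and at least one parent is homozygous. Intended
    as a paternity / sample-swap screen: unrelated individuals drop well
    below 1 at sites where the true parents are opposite homozygotes.
    Returns None (with a warning) when no site is informative.
    """
    mother_id, father_id, off_id = trio
    informative = 0
    consistent = 0
    for site in sites:
        calls = [site.calls.get(s) for s in trio]
        if any(c is None or c.is_missing for c in calls):
            continue
        confident = True
        for c in calls:
            if c.gq is None or c.gq < min_gq:
                confident = False
                break
            ab = minor_allele_balance(c)
            if ab is None:
                confident = False
                break
            if c.is_hom and ab >= hom_ab_max:
                confident = False
                break
            if c.is_het and ab < het_ab_min:
                confident = False
                break
        if not confident:
            continue
        mother, father, off = calls
        if not (mother.is_hom or father.is_hom):
            continue
        informative += 1
        if _transmission_consistent(mother.alleles, father.alleles, off.alleles):
            consistent += 1
    if informative == 0:
        warnings.warn("no informative sites for Mendelian consistency")
        return None
    return consistent / informative


def _transmission_consistent(
    mother: tuple[str, str], father: tuple[str, str], off: tuple[str, str]
) -> bool:
    a, b = off
    return (a in mother and b in father) or (b in mother and a in father)


_TSV_COLUMNS = [
    "contig", "position", "offspring_id", "parental_allele", "mutant_allele",
    "offspring_allele_balance", "substitution_class", "concordance_status",
    "validation_status", "parental_origin", "clustered",
]


def write_candidates_tsv(candidates: Sequence[CandidateDNM], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                f"{c.contig}\t{c.position}\t{c.offspring_id}\t{c.parental_allele}\t"
                f"{c.mutant_allele}\t{c.offspring_allele_balance:.6g}\t"
                f"{c.substitution_class}\t{c.concordance_status}\t{c.validation_status}\t"
                f"{c.parental_origin}\t{int(c.clustered)}\n"
            )


def read_candidates_tsv(path) -> list[CandidateDNM]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                CandidateDNM(
                    contig=row["contig"],
                    position=int(row["position"]),
                    offspring_id=row["offspring_id"],
                    parental_allele=row["parental_allele"],
                    mutant_allele=row["mutant_allele"],
                    offspring_allele_balance=float(row["offspring_allele_balance"]),
                    substitution_class=row["substitution_class"],
                    concordance_status=row["concordance_status"],
                    validation_status=row["validation_status"],
                    parental_origin=row["parental_origin"],
                    clustered=bool(int(row["clustered"])),
                )
            )
    return out


def apply_validation_statuses(
    candidates: Sequence[CandidateDNM], statuses: Mapping[tuple[str, int, str], str]
) -> list[CandidateDNM]:
    """Merge externally determined validation outcomes keyed by
    (contig, position, offspring_id); unknown keys stay untouched."""
    out = []
    for c in candidates:
        status = statuses.get(c.key)
        out.append(replace(c, validation_status=status) if status else c)
    return out


def summarize_validation(candidates: Sequence[CandidateDNM]) -> dict:
    """Validation tallies and the false positive rate.

    FPR = 100 x refuted / (confirmed + refuted); unvalidated candidates are
    excluded from the denominator but reported. Zero validated candidates
    leaves the FPR undefined (None, with a warning).
    """
    n_confirmed = sum(1 for c in candidates if c.validation_status == "confirmed")
    n_refuted = sum(1 for c in candidates if c.validation_status == "refuted")
    n_unvalidated = sum(1 for c in candidates if c.validation_status == "unvalidated")
    n_validated = n_confirmed + n_refuted
    if n_validated == 0:
        warnings.warn("no validated candidates; false positive rate undefined")
        fpr = None
    else:
        fpr = 100.0 * n_refuted / n_validated
    return {
        "n_candidates": len(candidates),
        "n_validated": n_validated,
        "n_confirmed": n_confirmed,
        "n_refuted": n_refuted,
        "n_unvalidated": n_unvalidated,
        "false_positive_rate_percent": fpr,
    }
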