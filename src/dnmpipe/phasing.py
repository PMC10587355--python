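"""Read-backed assignment of the parental origin of a de novo mutation.

A DNM sits on one of the offspring's two haplotypes. At flanking sites where
the parents are homozygous for different alleles, the offspring's two
haplotypes carry one maternal and one paternal allele, so any read fragment
linking the mutant allele to such an informative allele votes for the
gamete of origin.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .dnm_calling import CandidateDNM
from .pedigree_data import (
    BIALLELIC_SNP,
    Pedigree,
    SiteRecord,
    minor_allele_balance,
)

__all__ = [
    "ReadFragment",
    "InformativeSite",
    "find_informative_sites",
    "assign_parental_origin",
]


@dataclass(frozen=True)
class ReadFragment:
    """A read or mate pair projected onto variant positions."""

    fragment_id: str
    observations: tuple[tuple[str, int, str], ...]  # (contig, 1-based pos, allele)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("fragment must carry at least one observation")
        keys = [(c, p) for c, p, _ in self.observations]
        if len(set(keys)) != len(keys):
            raise ValueError(f"fragment {self.fragment_id}: duplicate positions")

    def allele_at(self, contig: str, position: int) -> str | None:
        for c, p, a in self.observations:
            if c == contig and p == position:
                return a
        return None


def read_fragments_tsv(path) -> list[ReadFragment]:
    """Read fragments from a TSV with columns fragment_id, contig, position,
    allele (one observation per row)."""
    import csv

    obs_by_id: dict[str, list[tuple[str, int, str]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            fid = row["fragment_id"]
            if fid not in obs_by_id:
                obs_by_id[fid] = []
                order.append(fid)
            obs_by_id[fid].append((row["contig"], int(row["position"]), row["allele"]))
    return [ReadFragment(fid, tuple(obs_by_id[fid])) for fid in order]


@dataclass(frozen=True)
class InformativeSite:
    contig: str
    position: int  # 1-based
    maternal_allele: str
    paternal_allele: str


def find_informative_sites(
    sites: Iterable[SiteRecord],
    pedigree: Pedigree,
    anchor_contig: str,
    anchor_position: int,
    max_distance: int = 1000,
    min_gq: float = 20.0,
    hom_ab_max: float = 0.1,
) -> list[InformativeSite]:
    """Sites within max_distance of a DNM where the parents are confidently
    homozygous for different alleles, annotated with which allele is
    maternal and which paternal. Often empty — segregating sites near a DNM
    are the exception, not the rule."""
    out: list[InformativeSite] = []
    for site in sites:
        if site.contig != anchor_contig or site.position == anchor_position:
            continue
        if abs(site.position - anchor_position) > max_distance:
            continue
        if site.site_class != BIALLELIC_SNP:
            continue
        mother = site.calls.get(pedigree.mother_id)
        father = site.calls.get(pedigree.father_id)
        ok = True
        for call in (mother, father):
            if call is None or call.is_missing or not call.is_hom:
                ok = False
                break
            if call.gq is None or call.gq < min_gq:
                ok = False
                break
            ab = minor_allele_balance(call)
            if ab is None or ab >= hom_ab_max:
                ok = False
                break
        if not ok or mother.alleles[0] == father.alleles[0]:
            continue
        out.append(
            InformativeSite(
                contig=site.contig,
                position=site.position,
                maternal_allele=mother.alleles[0],
                paternal_allele=father.alleles[0],
            )
        )
    return out


def assign_parental_origin(
    dnm: CandidateDNM,
    fragments: Iterable[ReadFragment],
    informative: Sequence[InformativeSite],
    min_support: int = 2,
    min_agreement: float = 0.9,
) -> tuple[str, dict]:
    """Vote over fragments that carry the mutant allele and overlap at least
    one informative site.

    A fragment votes maternal/paternal by the majority of its informative
    observations (ties abstain); fragments carrying the non-mutant allele at
    the DNM position never vote. The origin is assigned when at least
    ``min_support`` fragments vote and at least ``min_agreement`` of them
    agree; otherwise 'undetermined'.
    """
    by_pos = {(s.contig, s.position): s for s in informative}
    maternal_votes = 0
    paternal_votes = 0
    for frag in fragments:
        dnm_allele = frag.allele_at(dnm.contig, dnm.position)
        if dnm_allele != dnm.mutant_allele:
            continue
        m = p = 0
        for contig, pos, allele in frag.observations:
            info = by_pos.get((contig, pos))
            if info is None:
                continue
            if allele == info.maternal_allele:
                m += 1
            elif allele == info.paternal_allele:
                p += 1
        if m > p:
            maternal_votes += 1
        elif p > m:
            paternal_votes += 1
    total = maternal_votes + paternal_votes
    support = {"maternal_votes": maternal_votes, "paternal_votes": paternal_votes}
    if total >= min_support:
        if maternal_votes / total >= min_agreement:
            return "maternal", support
        if paternal_votes / total >= min_agreement:
            return "paternal", support
    return "undetermined", support
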