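"""Shared builders for hand-constructed genotype fixtures."""
from __future__ import annotations

from dnmpipe.callability import ThresholdSet
from dnmpipe.pedigree_data import GenotypeCall, SiteRecord


def call(alleles, ad=None, dp=None, gq=99):
    """GenotypeCall shorthand: call(('A','G'), (14, 12))."""
    if alleles is None:
        return GenotypeCall(None, None, None, None)
    if ad is not None and dp is None:
        dp = sum(ad)
    return GenotypeCall(tuple(alleles), tuple(ad) if ad else None, dp, gq)


def site(pos, calls, ref="A", alts=("G",), contig="c1", mq=60.0, qd=20.0,
         bq=0.0, rp=0.0):
    """SiteRecord shorthand with permissive default annotations."""
    return SiteRecord(
        contig=contig,
        position=pos,
        ref_allele=ref,
        alt_alleles=tuple(alts),
        calls=dict(calls),
        mapping_quality=mq,
        quality_by_depth=qd,
        base_quality_rank_sum=bq,
        read_position_rank_sum=rp,
    )


def permissive_thresholds(samples, depth=(0.0, 10_000.0)):
    """A ThresholdSet that never rejects (for tests isolating other rules)."""
    return ThresholdSet(
        base_quality_rank_sum=(-100.0, 100.0),
        read_position_rank_sum=(-100.0, 100.0),
        mapping_quality_low=0.0,
        quality_by_depth_low=0.0,
        depth={s: depth for s in samples},
        n_sites=1000,
    )


import numpy as np

from dnmpipe.dnm_calling import CandidateDNM
from dnmpipe.phasing import InformativeSite, assign_parental_origin


def score_phasing(sim, pileups):
    """Assign origins for every planted DNM using true parental genotypes as
    the informative map and the simulated fragments as evidence."""
    cfg = sim.config
    n_assigned = n_correct = 0
    H = sim.H
    for d in sim.truth.dnms:
        gpos = cfg.global_position(d.contig, d.position - 1)
        near = np.flatnonzero(np.abs(sim.pos - gpos) <= cfg.fragment_length)
        informative = []
        for j in near.tolist():
            mom = H[0, 0, j] + H[0, 1, j]
            dad = H[1, 0, j] + H[1, 1, j]
            if {mom, dad} == {0, 2}:
                contig, local = cfg.locus(int(sim.pos[j]))
                from dnmpipe.synthetic import BASES  # noqa: local import kept cheap

                mat = str(BASES[sim.alt[j] if mom == 2 else sim.ref[j]])
                pat = str(BASES[sim.alt[j] if dad == 2 else sim.ref[j]])
                informative.append(InformativeSite(contig, local + 1, mat, pat))
        if not informative:
            continue
        cand = CandidateDNM(
            contig=d.contig, position=d.position, offspring_id=d.offspring_id,
            parental_allele=d.ref, mutant_allele=d.alt,
            offspring_allele_balance=0.5, substitution_class="transition"
            if {d.ref, d.alt} in ({"A", "G"}, {"C", "T"}) else "transversion",
        )
        frags = [f for f in pileups.fragments
                 if f.fragment_id.startswith(f"{d.offspring_id}:{d.contig}:{d.position}:")]
        origin, _ = assign_parental_origin(cand, frags, informative)
        if origin != "undetermined":
            n_assigned += 1
            if origin == d.origin:
                n_correct += 1
    return n_assigned, n_correct
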