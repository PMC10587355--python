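"""Vectorised in-memory pipeline over simulated pedigrees.

Implements the same filter chain as the record-stream operations in
``callability`` and ``dnm_calling`` — high-confidence het extraction,
percentile thresholds, per-trio callability, Mendelian-violation candidate
calling with dual-caller concordance, spike-in FNR and windowed diversity —
directly on the simulator's arrays. This is the engine behind whole-genome
synthetic experiments and Monte-Carlo studies; an integration test pins its
output to the record-stream implementation run on the emitted VCFs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .callability import ThresholdSet
from .dnm_calling import CandidateDNM, classify_substitution
from .pedigree_data import IntervalSet
from .rate_estimation import RateEstimate, estimate_rate
from .synthetic import (
    BASES,
    CallSet,
    PedigreeSim,
    PileupSet,
    SimConfig,
    call_from_counts,
    call_genotypes,
    gq_homref,
    simulate_pedigree,
    substream,
)

__all__ = ["PipelineResult", "run_full_pipeline"]


@dataclass
class PipelineResult:
    """Everything a synthetic end-to-end run produces."""

    config: SimConfig
    sim: PedigreeSim
    pileups: PileupSet
    calls_primary: CallSet
    calls_secondary: CallSet
    mask: IntervalSet
    hc_count: int
    thresholds: ThresholdSet
    callable_counts: dict[str, int]
    S: int
    candidates: list[CandidateDNM]
    m: int
    n_true_detected: int
    n_false_positive: int
    n_planted: int
    fnr: dict | None
    rate: RateEstimate | None
    mean_pi: float | None
    ne_hat: float | None
    spike_vafs: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_detected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    trio_callable: np.ndarray | None = None  # (n_offspring, L) bool
    member_pass: np.ndarray | None = None  # (n_samples, L) bool
    site_pass: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "n_planted": self.n_planted,
            "hc_sites": self.hc_count,
            "callable_counts": dict(self.callable_counts),
            "S": self.S,
            "n_candidates": len(self.candidates),
            "m": self.m,
            "n_true_detected": self.n_true_detected,
            "n_false_positive": self.n_false_positive,
            "fnr": None if self.fnr is None else self.fnr["fnr"],
            "rate": None if self.rate is None else self.rate.as_dict(),
            "mean_pi": self.mean_pi,
            "ne_hat": self.ne_hat,
        }


def _minor_ab(ad_ref: np.ndarray, ad_alt: np.ndarray) -> np.ndarray:
    """Minor allele balance over the two site alleles; NaN when no reads."""
    den = (ad_ref + ad_alt).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, np.minimum(ad_ref, ad_alt) / den, np.nan)


def _mask_array(mask: IntervalSet, config: SimConfig) -> np.ndarray:
    arr = np.zeros(config.genome_length, dtype=bool)
    for name, cstart, cend in config.contig_bounds():
        for s, e in mask.intervals(name):
            arr[cstart + int(s) : min(cstart + int(e), cend)] = True
    return arr


def run_full_pipeline(
    config: SimConfig,
    n_spikes: int = 947,
    level: float = 0.95,
    window_size: int = 100_000,
    min_gq: float = 20.0,
    hom_ab_max: float = 0.1,
    het_ab_min: float = 0.25,
    min_mutant_ab: float = 0.25,
    percentile_low: float = 5.0,
    percentile_high: float = 95.0,
    min_hc_sites: int = 100,
    extra_mask: IntervalSet | None = None,
    compute_pi: bool = True,
    spike_offspring: str | None = None,
    keep_arrays: bool = False,
) -> PipelineResult:
    """Simulate a pedigree and run the whole detection/estimation pipeline.

    Stages: simulate founders/transmission/pileups, call genotypes with both
    emulated callers, extract high-confidence het sites, derive percentile
    thresholds, count per-trio callable sites, call concordant
    Mendelian-violation candidates, estimate the FNR by spiking ``n_spikes``
    invariant callable sites in one offspring, and convert to the corrected
    rate with its Poisson CI (plus parental diversity and Ne).
    """
    sim = simulate_pedigree(config)
    pileups = PileupSet(sim)
    cp = call_genotypes(pileups, "primary")
    cs = call_genotypes(pileups, "secondary")
    samples = pileups.samples
    S_n = len(samples)
    L = config.genome_length

    mask = sim.founders.repeat_mask
    if extra_mask is not None:
        mask = mask.union(extra_mask)
    mask_arr = _mask_array(mask, config)

    gpos = cp.var_gpos
    n_var = gpos.size
    ab_min = _minor_ab(cp.AD_ref, cp.AD_alt)  # (S, n)
    gt, gq = cp.GT, cp.GQ
    unmasked_var = ~mask_arr[gpos]

    # ---- high-confidence het sites ----------------------------------------
    all_called = (gt >= 0).all(axis=0) & (gq >= min_gq).all(axis=0)
    par_opp_hom = (
        ((gt[0] == 0) & (gt[1] == 2)) | ((gt[0] == 2) & (gt[1] == 0))
    )
    with np.errstate(invalid="ignore"):
        par_ab_ok = (ab_min[0] < hom_ab_max) & (ab_min[1] < hom_ab_max)
        off_het = (gt[2:] == 1).all(axis=0) & (ab_min[2:] >= het_ab_min).all(axis=0)
    hc = cp.has_alt & unmasked_var & all_called & par_opp_hom & par_ab_ok & off_het
    hc_idx = np.flatnonzero(hc)
    if hc_idx.size < min_hc_sites:
        raise ValueError(
            f"only {hc_idx.size} high-confidence het sites; need at least {min_hc_sites}"
        )

    # ---- thresholds ---------------------------------------------------------
    pcts = [percentile_low, percentile_high]
    bq_b = tuple(np.percentile(cp.bq[hc_idx], pcts))
    rp_b = tuple(np.percentile(cp.rp[hc_idx], pcts))
    mq_lo = float(np.percentile(cp.mq_var[hc_idx], percentile_low))
    qd_lo = float(np.percentile(cp.qd[hc_idx], percentile_low))
    depth_bounds = {}
    hc_gpos = gpos[hc_idx]
    for s, name in enumerate(samples):
        lo, hi = np.percentile(pileups.depth[s, hc_gpos], pcts)
        depth_bounds[name] = (float(lo), float(hi))
    thresholds = ThresholdSet(
        base_quality_rank_sum=(float(bq_b[0]), float(bq_b[1])),
        read_position_rank_sum=(float(rp_b[0]), float(rp_b[1])),
        mapping_quality_low=mq_lo,
        quality_by_depth_low=qd_lo,
        depth=depth_bounds,
        n_sites=int(hc_idx.size),
    )

    # ---- per-sample and per-site pass arrays -------------------------------
    member_pass = np.zeros((S_n, L), dtype=bool)
    err_by_sample: dict[int, np.ndarray] = {}
    for s, name in enumerate(samples):
        d = pileups.depth[s]
        gq_genome = gq_homref(d, cp.eps_model, cp.log_priors).astype(np.int32)
        rows = np.flatnonzero(cp.err_sample == s)
        err_by_sample[s] = rows
        if rows.size:
            gq_genome[cp.err_gpos[rows]] = cp.err_gq[rows]
        gq_genome[gpos] = gq[s]
        lo, hi = thresholds.depth[name]
        member_pass[s] = (d > 0) & (gq_genome >= min_gq) & (d >= lo) & (d <= hi)

    ann_pass_var = (
        (cp.bq >= bq_b[0]) & (cp.bq <= bq_b[1])
        & (cp.rp >= rp_b[0]) & (cp.rp <= rp_b[1])
        & (cp.mq_var >= mq_lo) & (cp.qd >= qd_lo)
        & unmasked_var
    )
    site_pass = (pileups.mq >= mq_lo) & ~mask_arr
    emitted = cp.has_alt
    site_pass[gpos[emitted]] = ann_pass_var[emitted]

    # ---- per-trio callability ----------------------------------------------
    n_off = config.n_offspring
    parents_pass = member_pass[0] & member_pass[1]
    trio_callable = np.zeros((n_off, L), dtype=bool)
    callable_counts: dict[str, int] = {}
    for k in range(n_off):
        trio_callable[k] = site_pass & parents_pass & member_pass[2 + k]
        callable_counts[samples[2 + k]] = int(trio_callable[k].sum())
    S_total = sum(callable_counts.values())

    # ---- Mendelian-violation candidates ------------------------------------
    with np.errstate(invalid="ignore"):
        par_hom_same = (
            emitted & unmasked_var
            & (gt[0] == gt[1]) & ((gt[0] == 0) | (gt[0] == 2))
            & (gq[0] >= min_gq) & (gq[1] >= min_gq)
            & (ab_min[0] < hom_ab_max) & (ab_min[1] < hom_ab_max)
        )
    candidates: list[CandidateDNM] = []
    truth_keys = sim.truth.dnm_keys()
    sec_col = np.searchsorted(cs.var_gpos, gpos)
    sec_col = np.clip(sec_col, 0, max(cs.var_gpos.size - 1, 0))
    in_sec = (cs.var_gpos.size > 0) & (cs.var_gpos[sec_col] == gpos)

    def secondary_gt(s: int, j: int) -> int:
        if in_sec[j]:
            return int(cs.GT[s, sec_col[j]])
        # invariant for the secondary caller: hom-ref when covered
        return 0 if pileups.depth[s, gpos[j]] > 0 else -1

    for k in range(n_off):
        s_off = 2 + k
        with np.errstate(invalid="ignore"):
            cand = (
                par_hom_same
                & (gt[s_off] == 1)
                & (ab_min[s_off] >= min_mutant_ab)
                & trio_callable[k][gpos]
            )
        for j in np.flatnonzero(cand).tolist():
            parental_code = cp.var_ref[j] if gt[0, j] == 0 else cp.var_alt[j]
            mutant_code = cp.var_alt[j] if gt[0, j] == 0 else cp.var_ref[j]
            concordant = all(
                secondary_gt(s, j) == int(gt[s, j]) for s in (0, 1, s_off)
            )
            contig, local = config.locus(int(gpos[j]))
            key = (contig, local + 1, samples[s_off])
            candidates.append(
                CandidateDNM(
                    contig=contig,
                    position=local + 1,
                    offspring_id=samples[s_off],
                    parental_allele=str(BASES[parental_code]),
                    mutant_allele=str(BASES[mutant_code]),
                    offspring_allele_balance=float(ab_min[s_off, j]),
                    substitution_class=classify_substitution(
                        str(BASES[parental_code]), str(BASES[mutant_code])
                    ),
                    concordance_status="concordant" if concordant else "discordant",
                    validation_status="confirmed" if key in truth_keys else "refuted",
                )
            )
    by_site: dict[tuple[str, int], int] = {}
    for c in candidates:
        by_site[(c.contig, c.position)] = by_site.get((c.contig, c.position), 0) + 1
    for c in candidates:
        c.clustered = by_site[(c.contig, c.position)] > 1

    concordant_cands = [c for c in candidates if c.concordance_status == "concordant"]
    n_true = sum(1 for c in concordant_cands if c.validation_status == "confirmed")
    n_fp = sum(1 for c in concordant_cands if c.validation_status == "refuted")
    m = n_true  # validated against simulator truth; refuted candidates excluded

    # ---- spike-in FNR -------------------------------------------------------
    fnr_result = None
    spike_vafs = np.empty(0)
    spike_detected = np.empty(0, dtype=bool)
    if n_spikes > 0:
        focal = spike_offspring or samples[2]
        focal_s = samples.index(focal)
        focal_k = focal_s - 2
        elig = trio_callable[focal_k].copy()
        elig[gpos] = False
        pool = np.flatnonzero(elig)
        n_use = int(min(n_spikes, pool.size))
        if n_use > 0:
            rng = substream(config.seed, "spikes")
            spots = np.sort(rng.choice(pool, size=n_use, replace=False))
            hc_off_den = (cp.AD_ref[focal_s, hc_idx] + cp.AD_alt[focal_s, hc_idx])
            ok = hc_off_den > 0
            vaf_source = cp.AD_alt[focal_s, hc_idx][ok] / hc_off_den[ok]
            spike_vafs = rng.choice(vaf_source, size=n_use, replace=True)

            err_lookup: dict[tuple[int, int], int] = {}
            sel = np.isin(cp.err_gpos, spots)
            for row in np.flatnonzero(sel).tolist():
                err_lookup[(int(cp.err_sample[row]), int(cp.err_gpos[row]))] = int(
                    cp.pileups.err_count[row]
                )

            d_off = pileups.depth[focal_s, spots].astype(np.int64)
            e_off = np.array([err_lookup.get((focal_s, int(p)), 0) for p in spots])
            k_alt = np.rint(spike_vafs * d_off).astype(np.int64)
            k_alt = np.minimum(k_alt, d_off - e_off)
            r_off = d_off - e_off - k_alt
            gt_p, gq_p = call_from_counts(r_off, k_alt, cp.eps_model, cp.log_priors)
            gt_s, _ = call_from_counts(r_off, k_alt, cs.eps_model, cs.log_priors)
            ab = _minor_ab(r_off, k_alt)
            bq_sp, rp_sp, qd_sp = pileups.annotations_for(spots)
            ann_ok = (
                (bq_sp >= bq_b[0]) & (bq_sp <= bq_b[1])
                & (rp_sp >= rp_b[0]) & (rp_sp <= rp_b[1])
                & (qd_sp >= qd_lo)
            )  # MQ already passed via callability of the site
            with np.errstate(invalid="ignore"):
                spike_detected = (
                    (gt_p == 1) & (gt_s == 1) & (gq_p >= min_gq)
                    & (ab >= min_mutant_ab) & ann_ok
                )
            fnr_result = {
                "n_planted": int(n_use),
                "n_detected": int(spike_detected.sum()),
                "fnr": float((n_use - spike_detected.sum()) / n_use),
            }

    # ---- rate, diversity, Ne ------------------------------------------------
    fnr_value = fnr_result["fnr"] if fnr_result else 0.0
    rate = estimate_rate(m, S_total, fnr_value, level) if S_total > 0 else None

    mean_pi = None
    ne_hat = None
    if compute_pi:
        mean_pi = _parental_pi(
            config, pileups, cp, site_pass, member_pass, window_size
        )
        if rate is not None and rate.mu_corrected > 0 and mean_pi is not None:
            ne_hat = mean_pi / (4.0 * rate.mu_corrected)

    return PipelineResult(
        config=config,
        sim=sim,
        pileups=pileups,
        calls_primary=cp,
        calls_secondary=cs,
        mask=mask,
        hc_count=int(hc_idx.size),
        thresholds=thresholds,
        callable_counts=callable_counts,
        S=S_total,
        candidates=candidates,
        m=m,
        n_true_detected=n_true,
        n_false_positive=n_fp,
        n_planted=len(sim.truth.dnms),
        fnr=fnr_result,
        rate=rate,
        mean_pi=mean_pi,
        ne_hat=ne_hat,
        spike_vafs=spike_vafs,
        spike_detected=spike_detected,
        trio_callable=trio_callable if keep_arrays else None,
        member_pass=member_pass if keep_arrays else None,
        site_pass=site_pass if keep_arrays else None,
    )


def evaluate_spike_plan(result: PipelineResult, plan) -> dict:
    """Re-run detection at an externally supplied spike plan's sites.

    ``result`` must come from :func:`run_full_pipeline` with
    ``keep_arrays=True`` (the plan is judged against that run's thresholds
    and callability). Returns the FNR report for the plan.
    """
    if result.trio_callable is None:
        raise ValueError("run_full_pipeline(..., keep_arrays=True) required")
    config = result.config
    cp, cs = result.calls_primary, result.calls_secondary
    thr = result.thresholds
    samples = result.pileups.samples
    n_detected = 0
    err_lookup = {
        (int(cp.err_sample[i]), int(cp.err_gpos[i])): int(result.pileups.err_count[i])
        for i in range(cp.err_gpos.size)
    }
    for s in plan.sites:
        s_idx = samples.index(s.target_sample)
        k_off = s_idx - 2
        gpos = config.global_position(s.contig, s.position - 1)
        if not result.trio_callable[k_off][gpos]:
            continue
        d = int(result.pileups.depth[s_idx, gpos])
        e = err_lookup.get((s_idx, gpos), 0)
        k_alt = min(int(np.rint(s.target_vaf * d)), d - e)
        r = d - e - k_alt
        gt_p, gq_p = call_from_counts(
            np.array([r]), np.array([k_alt]), cp.eps_model, cp.log_priors
        )
        gt_s, _ = call_from_counts(
            np.array([r]), np.array([k_alt]), cs.eps_model, cs.log_priors
        )
        ab = min(r, k_alt) / (r + k_alt) if (r + k_alt) > 0 else float("nan")
        bq, rp, qd = result.pileups.annotations_for(np.array([gpos]))
        ann_ok = (
            thr.base_quality_rank_sum[0] <= bq[0] <= thr.base_quality_rank_sum[1]
            and thr.read_position_rank_sum[0] <= rp[0] <= thr.read_position_rank_sum[1]
            and qd[0] >= thr.quality_by_depth_low
        )
        if (
            int(gt_p[0]) == 1 and int(gt_s[0]) == 1 and int(gq_p[0]) >= 20
            and not np.isnan(ab) and ab >= 0.25 and ann_ok
        ):
            n_detected += 1
    n = len(plan.sites)
    return {"n_planted": n, "n_detected": n_detected,
            "fnr": (n - n_detected) / n if n else float("nan")}


def _parental_pi(
    config: SimConfig,
    pileups: PileupSet,
    cp: CallSet,
    site_pass: np.ndarray,
    member_pass: np.ndarray,
    window_size: int,
    min_callable_frac: float = 0.1,
) -> float | None:
    """Callable-site-weighted heterozygosity of the two parents in
    non-overlapping windows."""
    het_total = 0
    call_total = 0
    gpos = cp.var_gpos
    for s in (0, 1):
        callable_s = site_pass & member_pass[s]
        het_var = (cp.GT[s] == 1) & callable_s[gpos]
        for name, cstart, cend in config.contig_bounds():
            n_win = -(-(cend - cstart) // window_size)
            local_call = callable_s[cstart:cend]
            widx = np.arange(cend - cstart) // window_size
            n_call = np.bincount(widx, weights=local_call, minlength=n_win)
            sel = (gpos >= cstart) & (gpos < cend) & het_var
            wvar = (gpos[sel] - cstart) // window_size
            n_het = np.bincount(wvar, minlength=n_win)
            keep = n_call >= min_callable_frac * window_size
            het_total += int(n_het[keep].sum())
            call_total += int(n_call[keep].sum())
    if call_total == 0:
        return None
    return het_total / call_total
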