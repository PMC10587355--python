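"""Mutation-rate, diversity and effective-population-size estimation.

The per-generation single-base mutation rate is mu = m / (2S), where m is
the number of de novo mutations and S the total number of callable sites
summed over trios (each diploid trio screens two copies of every callable
site). The rate is corrected for the spike-in-estimated false negative rate
by dividing by (1 - FNR), and interval-estimated by treating m as Poisson:
the bounds are the smallest integers whose Poisson CDF at mean m reaches
alpha/2 and 1 - alpha/2, divided by 2S(1 - FNR). Nucleotide diversity pi for
a diploid individual is the fraction of callable sites that are
heterozygous, computed in non-overlapping windows; at neutral equilibrium
pi = 4 Ne mu gives the long-term effective population size Ne = pi / (4 mu).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callability import ThresholdSet, site_filters_pass
from .pedigree_data import (
    BIALLELIC_SNP,
    MONOMORPHIC,
    IntervalSet,
    SiteRecord,
)

__all__ = [
    "RateEstimate",
    "DiversityEstimate",
    "point_rate",
    "correct_rate",
    "poisson_ci",
    "estimate_rate",
    "windowed_pi",
    "effective_population_size",
    "expected_newborn_dnms",
]


def point_rate(m: int, S: int) -> float:
    """Raw per-bp per-generation rate m / (2S)."""
    if S <= 0:
        raise ValueError("S must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    return m / (2.0 * S)


def correct_rate(mu_raw: float, fnr: float) -> float:
    """Divide the raw rate by (1 - FNR)."""
    if not 0.0 <= fnr < 1.0:
        raise ValueError("fnr must lie in [0, 1)")
    return mu_raw / (1.0 - fnr)


def poisson_ci(m: int, S: int, fnr: float = 0.0, level: float = 0.95) -> tuple[float, float]:
    """Poisson-quantile confidence interval for the corrected rate.

    k_low (k_high) is the smallest integer k with Poisson CDF(k; m) >=
    alpha/2 (resp. >= 1 - alpha/2); the bounds are k / (2S(1 - FNR)).
    m = 0 yields the degenerate (0, 0) interval, with a warning.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if m == 0:
        warnings.warn("m = 0: Poisson(0) is a point mass; returning degenerate (0, 0) CI")
        return (0.0, 0.0)
    alpha = 1.0 - level
    k_low = int(stats.poisson.ppf(alpha / 2.0, m))
    k_high = int(stats.poisson.ppf(1.0 - alpha / 2.0, m))
    denom = 2.0 * S * (1.0 - fnr)
    return (k_low / denom, k_high / denom)


@dataclass(frozen=True)
class RateEstimate:
    """Mutation count, callable-site total, FNR and derived rates."""

    m: int
    S: int
    fnr: float
    mu_raw: float
    mu_corrected: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "m": self.m,
            "S": self.S,
            "fnr": self.fnr,
            "mu_raw": self.mu_raw,
            "mu_corrected": self.mu_corrected,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


def estimate_rate(m: int, S: int, fnr: float = 0.0, level: float = 0.95) -> RateEstimate:
    """Assemble the full FNR-corrected rate estimate with its Poisson CI."""
    mu_raw = point_rate(m, S)
    mu_corrected = correct_rate(mu_raw, fnr)
    lo, hi = poisson_ci(m, S, fnr, level)
    return RateEstimate(
        m=m, S=S, fnr=fnr, mu_raw=mu_raw, mu_corrected=mu_corrected,
        ci_low=lo, ci_high=hi, level=level,
    )


@dataclass
class DiversityEstimate:
    """Windowed per-sample nucleotide diversity.

    ``windows`` has one row per (sample, window): contig, start, end,
    n_callable, n_het, pi. ``mean_pi`` is the callable-site-weighted mean
    over all retained windows and samples.
    """

    windows: pd.DataFrame
    mean_pi: float
    per_sample: dict[str, float]


def _sample_callable(site: SiteRecord, sample: str, thresholds: ThresholdSet,
                     mask: IntervalSet, min_gq: float) -> bool:
    if site.site_class not in (MONOMORPHIC, BIALLELIC_SNP):
        return False
    if mask.contains(site.contig, site.position - 1):
        return False
    if not site_filters_pass(site, thresholds):
        return False
    call = site.calls.get(sample)
    if call is None or call.is_missing or call.gq is None or call.gq < min_gq:
        return False
    if call.total_depth is None:
        return False
    lo, hi = thresholds.depth[sample]
    return lo <= call.total_depth <= hi


def windowed_pi(
    sites: Iterable[SiteRecord],
    samples: Sequence[str],
    thresholds: ThresholdSet,
    mask: IntervalSet,
    window_size: int = 100_000,
    min_callable_frac: float = 0.1,
    min_gq: float = 20.0,
) -> DiversityEstimate:
    """Per-sample heterozygosity in non-overlapping windows.

    pi in a window = heterozygous callable sites / callable sites, the
    within-diploid-individual average pairwise difference per site. The
    denominator includes invariant callable sites — the property that
    motivates carrying monomorphic sites through the pipeline. Windows whose
    callable count falls below ``min_callable_frac`` x window_size are
    skipped. ``mean_pi`` weights windows by their callable counts.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counters: dict[tuple[str, str, int], list[int]] = {}
    for site in sites:
        w = (site.position - 1) // window_size
        for sample in samples:
            if not _sample_callable(site, sample, thresholds, mask, min_gq):
                continue
            key = (sample, site.contig, w)
            cnt = counters.setdefault(key, [0, 0])
            cnt[0] += 1
            if site.calls[sample].is_het:
                cnt[1] += 1
    if not counters:
        raise ValueError("no callable sites in any window")
    rows = []
    min_callable = min_callable_frac * window_size
    for (sample, contig, w), (n_call, n_het) in sorted(counters.items()):
        if n_call < min_callable:
            continue
        rows.append({
            "sample": sample,
            "contig": contig,
            "start": w * window_size,
            "end": (w + 1) * window_size,
            "n_callable": n_call,
            "n_het": n_het,
            "pi": n_het / n_call,
        })
    if not rows:
        raise ValueError(
            f"every window fell below the {min_callable_frac:.0%} callable-site minimum"
        )
    df = pd.DataFrame(rows)
    mean_pi = float(df["n_het"].sum() / df["n_callable"].sum())
    per_sample = {
        s: float(g["n_het"].sum() / g["n_callable"].sum())
        for s, g in df.groupby("sample")
    }
    return DiversityEstimate(windows=df, mean_pi=mean_pi, per_sample=per_sample)


def effective_population_size(pi: float, mu: float) -> float:
    """Long-term Ne = pi / (4 mu) from pi = 4 Ne mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return pi / (4.0 * mu)


def expected_newborn_dnms(mu: float, genome_length: float) -> float:
    """Expected single-base de novo mutations per diploid newborn: 2 mu G."""
    return 2.0 * mu * genome_length
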