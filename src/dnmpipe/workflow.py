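"""End-to-end pipeline runner, reporting and run manifests.

Two modes: the arithmetic mode converts a study's printed results-table
inputs (mutation count, callable total, spike-in tallies, validation
tallies, diversity) into the headline estimates; the synthetic mode runs
the full simulate -> filter -> call -> spike -> estimate chain from a seed.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .callability import masked_fraction
from .dnm_calling import write_candidates_tsv
from .rate_estimation import (
    effective_population_size,
    estimate_rate,
    expected_newborn_dnms,
)
from .synthetic import SimConfig
from .vectorized import PipelineResult, run_full_pipeline

__all__ = ["RunManifest", "paper_arithmetic_report", "run_pipeline"]


@dataclass
class RunManifest:
    """Provenance record: config snapshot, seed, content digests, timing."""

    tool_version: str
    master_seed: int
    config: dict
    digests: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def add_file(self, label: str, path: str | Path) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.digests[label] = h.hexdigest()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def paper_arithmetic_report(
    m: int,
    S: int,
    n_spike_planted: int,
    n_spike_detected: int,
    n_refuted: int,
    n_confirmed: int,
    pi: float,
    genome_length: float,
    masked_bases: int | None = None,
    assembly_length: int | None = None,
    level: float = 0.95,
) -> dict:
    """Headline numbers from a results table.

    Every quantity is recomputed from its printed inputs: FNR from the
    spike-in tallies, FPR from the validation tallies, the raw and
    FNR-corrected rates with the Poisson-quantile CI from (m, S, FNR), the
    expected de novo load of a newborn from the corrected rate and genome
    size, and Ne = pi / (4 mu).
    """
    if n_spike_planted <= 0:
        raise ValueError("spike-in tallies required for the FNR")
    fnr = (n_spike_planted - n_spike_detected) / n_spike_planted
    rate = estimate_rate(m, S, fnr, level)
    n_validated = n_refuted + n_confirmed
    fpr_percent = 100.0 * n_refuted / n_validated if n_validated else None
    report = {
        "m": m,
        "S": S,
        "fnr": fnr,
        "fnr_percent": round(100.0 * fnr, 1),
        "false_positive_rate_percent": fpr_percent,
        "mu_raw": rate.mu_raw,
        "mu_corrected": rate.mu_corrected,
        "ci_low": rate.ci_low,
        "ci_high": rate.ci_high,
        "level": level,
        "pi": pi,
        "ne": effective_population_size(pi, rate.mu_corrected),
        "expected_newborn_dnms": expected_newborn_dnms(rate.mu_corrected, genome_length),
    }
    if masked_bases is not None and assembly_length is not None:
        report["repeat_masked_percent"] = masked_fraction(masked_bases, assembly_length)
    return report


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path | None = None,
    n_spikes: int = 947,
    level: float = 0.95,
    window_size: int = 100_000,
    **pipeline_kwargs,
) -> tuple[RunManifest, dict]:
    """Synthetic end-to-end run: returns (manifest, report).

    The report carries per-trio callable counts, candidates, FNR, the rate
    estimate, diversity and Ne. When ``out_dir`` is given, report.json,
    thresholds.yaml, candidates.tsv and manifest.json are written there and
    digested into the manifest.
    """
    t0 = time.perf_counter()
    result: PipelineResult = run_full_pipeline(
        config, n_spikes=n_spikes, level=level, window_size=window_size,
        **pipeline_kwargs,
    )
    elapsed = time.perf_counter() - t0

    report = {
        "config": asdict(config),
        "truth": {
            "n_planted_dnms": result.n_planted,
            "n_founder_sites": result.sim.truth.n_founder_sites,
        },
        "hc_sites": result.hc_count,
        "callable_counts": result.callable_counts,
        "S": result.S,
        "candidates": [
            {
                "contig": c.contig,
                "position": c.position,
                "offspring_id": c.offspring_id,
                "parental_allele": c.parental_allele,
                "mutant_allele": c.mutant_allele,
                "substitution_class": c.substitution_class,
                "concordance_status": c.concordance_status,
                "validation_status": c.validation_status,
            }
            for c in result.candidates
        ],
        "m": result.m,
        "n_false_positive": result.n_false_positive,
        "fnr": result.fnr,
        "rate": None if result.rate is None else result.rate.as_dict(),
        "mean_pi": result.mean_pi,
        "ne_hat": result.ne_hat,
    }
    manifest = RunManifest(
        tool_version=__version__,
        master_seed=config.seed,
        config=asdict(config),
        timings_s={"pipeline": round(elapsed, 3)},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        thr_path = out / "thresholds.yaml"
        result.thresholds.to_yaml(thr_path)
        cand_path = out / "candidates.tsv"
        write_candidates_tsv(result.candidates, cand_path)
        for label, path in (
            ("report.json", report_path),
            ("thresholds.yaml", thr_path),
            ("candidates.tsv", cand_path),
        ):
            manifest.add_file(label, path)
        manifest.to_json(out / "manifest.json")
    return manifest, report
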