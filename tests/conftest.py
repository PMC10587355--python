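import pytest

from dnmpipe.synthetic import (
    PileupSet,
    SimConfig,
    call_genotypes,
    emit,
    simulate_pedigree,
)
from dnmpipe.vectorized import run_full_pipeline


@pytest.fixture(scope="session")
def small_cfg():
    """A pedigree small enough for record-stream processing but dense enough
    to clear the high-confidence-site minimum."""
    return SimConfig(
        seed=5,
        genome_length=30_000,
        target_pi=0.02,
        n_offspring=3,
        mu_true=5e-5,
        mean_depth_parents=20,
        mean_depth_offspring=15,
        error_rate=1e-3,
        fragment_length=500,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    return run_full_pipeline(small_cfg, n_spikes=0, compute_pi=False, keep_arrays=True)


@pytest.fixture(scope="session")
def emitted(small_run, tmp_path_factory):
    """The small run written to disk as VCFs/BEDs/TSVs."""
    out = tmp_path_factory.mktemp("simout")
    return emit(
        small_run.sim,
        small_run.pileups,
        small_run.calls_primary,
        small_run.calls_secondary,
        out,
    )


@pytest.fixture(scope="session")
def idealized_run():
    """Error-free, fixed-depth, unmasked: the exact-recovery regime."""
    cfg = SimConfig(
        seed=7,
        genome_length=200_000,
        target_pi=0.005,
        n_offspring=5,
        mu_true=2e-5,
        mean_depth_parents=60,
        mean_depth_offspring=60,
        error_rate=0.0,
        repeat_fraction=0.0,
        fixed_depth=True,
    )
    return run_full_pipeline(cfg, n_spikes=200)
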