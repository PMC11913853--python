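import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shrunk further for unit tests (seconds, not minutes)."""
    from tricross import sim

    params = sim.CohortParams(
        genome=sim.GenomeConfig(
            n_chrom=2, chrom_length_bp=20_000_000, chrom_length_cM=300.0,
            n_snps_per_chrom=300, n_genes_per_chrom=30,
        ),
        n_f1=12, n_f2=100,
        n_pleiotropic=4, n_eqtl_segregated=3, n_eqtl_background=3, n_line_de=8,
    )
    return sim.simulate_cohort(params, seed=7)


@pytest.fixture(scope="session")
def default_run():
    """One full-scale pipeline run at the study's default conditions."""
    from tricross import pipeline

    return pipeline.run_pipeline(pipeline.RunConfig(seed=1))
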