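import pytest

from tuarch.genome_io import EndProfile, GeneModel
from tuarch.pipeline import PipelineParams, run_pipeline
from tuarch.synthetic_data import SimConfig, simulate_all

# Benchmark conditions for recovery checks: 200 genes on a 400-kb genome,
# peaks of ~10 reads, 1-nt peak jitter, uniform background of 0.01 reads/nt.
RECOVERY_CONFIG = dict(
    seed=42,
    n_genes=200,
    genome_length=400_000,
    tss_peak_count_mean=10.0,
    tep_peak_count_mean=10.0,
    background_rate=0.01,
    peak_jitter_sd=1.0,
)


def profile(counts, strand="+", label="TAP_PLUS"):
    return EndProfile(label=label, strand=strand, counts=dict(counts))


@pytest.fixture
def gene_plus():
    return GeneModel("geneA", "+", 100, 1000)


@pytest.fixture(scope="session")
def noisy_sim():
    config = SimConfig(**RECOVERY_CONFIG)
    genome, truth, ends, cov = simulate_all(config)
    return config, genome, truth, ends, cov


@pytest.fixture(scope="session")
def noisy_result(noisy_sim):
    _, _, truth, ends, cov = noisy_sim
    return run_pipeline(
        truth.genes, ends, cov, PipelineParams(tss_coverage_filter="drop")
    )


@pytest.fixture(scope="session")
def noiseless_sim():
    config = SimConfig(
        **{
            **RECOVERY_CONFIG,
            "background_rate": 0.0,
            "peak_jitter_sd": 0.0,
            "tap_minus_processed_site_rate": 0.0,
            "noise_free": True,
        }
    )
    genome, truth, ends, cov = simulate_all(config)
    return config, genome, truth, ends, cov


@pytest.fixture(scope="session")
def noiseless_result(noiseless_sim):
    _, _, truth, ends, cov = noiseless_sim
    return run_pipeline(truth.genes, ends, cov)
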