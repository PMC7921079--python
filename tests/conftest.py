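import pytest
from hypothesis import HealthCheck, settings

from endoepi.pipeline import RunConfig, run_pipeline
from endoepi.synthetic_data import SimulationConfig, simulate_all

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: enough genes/probes for every stage to act."""
    return SimulationConfig(
        seed=5,
        n_genes=150,
        chrom_length=6_000_000,
        n_enhancers=40,
        n_promoter_dmrs=6,
        n_enhancer_dmrs=10,
        de_fraction=0.2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    """Full pipeline context for the small dataset, plus its run config."""
    data_dir = tmp_path_factory.mktemp("data")
    out_dir = tmp_path_factory.mktemp("out")
    small_dataset.write(data_dir)
    cfg = RunConfig(
        data_dir=str(data_dir),
        out_dir=str(out_dir),
        seed=5,
        markers=["G0000", "G0003", "NOT_A_GENE"],
    )
    ctx = run_pipeline(cfg)
    return small_dataset, ctx
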