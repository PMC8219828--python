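import pytest
from hypothesis import HealthCheck, settings

from ctsdimer.pipeline import analyze_study, recovery_metrics
from ctsdimer.synthetic_data import SimulationConfig, simulate_study

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast, reduced-scale study used by unit tests."""
    params = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=400_000,
        n_sites_1x=30,
        n_sites_2x=40,
        n_boris_only=8,
        n_decoy=12,
        n_genes=60,
        n_true_degs=20,
        pathway_size=10,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """The full-scale synthetic study at its default design."""
    return simulate_study(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_summary(default_study):
    return analyze_study(default_study, gsea_seed=101)


@pytest.fixture(scope="session")
def default_recovery(default_study):
    return recovery_metrics(default_study)
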