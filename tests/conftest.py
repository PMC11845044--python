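import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from meiomap.simulate import SimulationConfig, simulate_cross


@pytest.fixture(scope="session")
def small_config():
    """Two-chromosome cross with an introgression block: fast but non-trivial."""
    return SimulationConfig(
        chrom_lengths={"chr1": 400_000, "chr2": 300_000},
        background_marker_density=1.35,
        introgressions=[("chr1", 100_000, 180_000)],
        introgression_marker_density=3.225,
        co_per_meiosis=6.0,
        nco_per_meiosis=4.0,
        n_tetrads=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cross(small_config):
    return simulate_cross(small_config)


@pytest.fixture(scope="session")
def dense_clean_cross():
    """Error-free cross with dense markers: every stage should be near-lossless."""
    cfg = SimulationConfig(
        chrom_lengths={"chr1": 500_000},
        background_marker_density=5.0,
        co_per_meiosis=3.0,
        nco_per_meiosis=3.0,
        n_tetrads=30,
        seed=11,
    )
    return simulate_cross(cfg)
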