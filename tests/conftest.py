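import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fur_regulon_genome():
    """Synthetic chromosome embedding the published Fur regulon geometry."""
    from genomine.datasets import reconstruct_fur_genome

    return reconstruct_fur_genome(seed=0)


@pytest.fixture(scope="session")
def benchmark_genome():
    """The standard 100-kb planted-site validation chromosome."""
    from genomine.simulate import benchmark_genome_spec, simulate_genome

    return simulate_genome(benchmark_genome_spec(seed=11))


@pytest.fixture(scope="session")
def benchmark_proteomes():
    """Six proteomes evolved along the benchmark tree (tight A/B/C clade)."""
    from genomine.simulate import benchmark_tree_spec, simulate_proteomes

    return simulate_proteomes(benchmark_tree_spec(seed=5))
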