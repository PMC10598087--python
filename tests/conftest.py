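import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viropan import FamilySpec, ScoringScheme, all_vs_all, build_clusters, generate_family

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_family():
    """A 6-genome family with paralogs and orphans, plus its ground truth."""
    spec = FamilySpec(
        n_genomes=6, n_core=8, n_shell=3, n_cloud=4, paralog_rate=0.3,
        orphan_per_genome=1, seq_length_range=(80, 150), divergence=0.15, seed=7,
    )
    proteomes, truth = generate_family(spec)
    return spec, proteomes, truth


@pytest.fixture(scope="session")
def small_family_hits(small_family):
    _, proteomes, _ = small_family
    return all_vs_all(proteomes)


@pytest.fixture(scope="session")
def small_family_membership(small_family, small_family_hits):
    _, proteomes, _ = small_family
    return build_clusters(small_family_hits, proteomes)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
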