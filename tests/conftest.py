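import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epimem.annotation import GeneAnnotation
from epimem.synthetic import MemoryEffect, SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def plus_gene():
    return GeneAnnotation.from_body("GeneA", "GeneA", "chr1", "+", 10_000, 12_000)


@pytest.fixture
def minus_gene():
    return GeneAnnotation.from_body("GeneB", "GeneB", "chr1", "-", 8_001, 10_001)


@pytest.fixture
def small_cfg():
    """Scaled-down cohort for fast pipeline-level tests."""
    return SimConfig(
        seed=11,
        n_chrom=1,
        genes_per_chrom=60,
        n_gene_sets=6,
        genes_per_set=8,
        library_size_mean=1_000_000,
        memory_effect=MemoryEffect(effect_size=0.0),
    )
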