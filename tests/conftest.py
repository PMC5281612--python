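"""Shared fixtures and hypothesis profile for the test suite."""

import pytest
from hypothesis import HealthCheck, settings

from mirdiv import ContextModelConfig, MatureMiRNA, UtrRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def example_mirna() -> MatureMiRNA:
    """A 22-nt miRNA whose seed (GGAAUG) targets the DNA motif CATTCC."""
    return MatureMiRNA(name="mir1", sequence="UGGAAUGUAAAGAAGUAUGUAU")


@pytest.fixture
def example_utr(example_mirna) -> UtrRecord:
    """Carries a single 8mer site for ``example_mirna`` at [3, 11)."""
    return UtrRecord(gene_id="g1", taxon="A", sequence="GGGACATTCCAGGG")


@pytest.fixture
def default_scoring() -> ContextModelConfig:
    return ContextModelConfig()
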