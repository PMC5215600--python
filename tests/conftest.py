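import pytest

from qseq import (
    BarcodeConfig,
    SimulationConfig,
    mock_reference_taxa,
    simulate,
)


@pytest.fixture(scope="session")
def barcode8() -> BarcodeConfig:
    return BarcodeConfig(8)


@pytest.fixture(scope="session")
def references():
    return mock_reference_taxa()


@pytest.fixture(scope="session")
def small_sim(references):
    """Two-taxon error-free dataset: 300 templates each, 10x depth, seed 11."""
    refs = tuple(references[:2])
    config = SimulationConfig(
        taxa=refs,
        template_copies={r.taxon_id: 300 for r in refs},
        per_base_error=0.0,
        seed=11,
    )
    reads, truth = simulate(config)
    return config, reads, truth
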