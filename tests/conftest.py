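import pytest

from splicemir import (
    PipelineConfig,
    SimulationConfig,
    TranscriptCatalog,
    TranscriptModel,
    make_dataset,
)


@pytest.fixture
def cfg():
    return PipelineConfig(random_seed=0)


@pytest.fixture
def transcript_1kb():
    """1 kb transcript with CDS [100, 700): 5'UTR 100 nt, 3'UTR 300 nt."""
    return TranscriptModel("t1", "g1", length=1000, cds_start=100, cds_end=700)


@pytest.fixture(scope="session")
def small_bundle():
    """Small planted dataset shared by pipeline-level tests."""
    sim = SimulationConfig(
        n_genes=40, n_mirnas=6, n_samples=80, frac_regulated_pairs=0.4, seed=42
    )
    return make_dataset(sim)


@pytest.fixture
def two_transcript_catalog():
    cat = TranscriptCatalog()
    cat.add(TranscriptModel("tA", "g1", 1000, 100, 700))
    cat.add(TranscriptModel("tB", "g1", 900, 50, 600))
    return cat
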