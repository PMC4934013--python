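"""Shared fixtures: small deterministic synthetic datasets and hand-built
transcript models."""

import pytest

from riboscope.models import TranscriptModel
from riboscope.synthetic import SimulationConfig, simulate_annotation, simulate_footprints


def make_model(
    gene_id: str,
    transcript_id: str,
    utr5: str,
    cds: str,
    utr3: str,
    abundance: float = 1.0,
) -> TranscriptModel:
    """Build a transcript from explicit region sequences."""
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        sequence=utr5 + cds + utr3,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
        isoform_abundance=abundance,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=40, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    models, truth = simulate_annotation(small_config)
    return models, truth


@pytest.fixture(scope="session")
def small_footprints(small_config, small_dataset):
    models, truth = small_dataset
    reads, alignments = simulate_footprints(
        models, truth, small_config, depth=5000, with_reads=True
    )
    return reads, alignments
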