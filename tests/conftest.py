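import logging

import numpy as np
import pytest

from glori_dilution.annotation import TranscriptModel, Annotation
from glori_dilution.simulate import SimConfig, simulate_dataset

logging.disable(logging.CRITICAL)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 40 transcripts, 3 samples per group, seeded."""
    return SimConfig(n_transcripts=40, n_samples_per_group=3, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(reference, annotation, truth, data) for the small study."""
    return simulate_dataset(small_config)


@pytest.fixture
def toy_transcript():
    """UTR5=100, CDS=300, UTR3=200 on the plus strand."""
    return TranscriptModel(
        transcript_id="toy", contig="chrT", strand="+", tx_start=0,
        utr5_len=100, cds_len=300, utr3_len=200,
    )


@pytest.fixture
def toy_annotation(toy_transcript):
    minus = TranscriptModel(
        transcript_id="toy_minus", contig="chrM", strand="-", tx_start=0,
        utr5_len=100, cds_len=300, utr3_len=200,
    )
    return Annotation([toy_transcript, minus])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
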