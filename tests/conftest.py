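import numpy as np
import pytest

from utrvar.core_io import SnvRecord, TranscriptRecord
from utrvar.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic cohort, shared across the suite."""
    return generate_dataset(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(
        SimulationConfig(rng_seed=4, n_genes=12, n_snvs=24, n_mirnas=12)
    )


@pytest.fixture(scope="session")
def mirna_result(dataset):
    """Full target-site cascade on the shared cohort."""
    from utrvar.mirna import run_mirna_pipeline

    return run_mirna_pipeline(
        dataset.snvs, dataset.transcripts, dataset.mirnas, dataset.annotations
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_transcript():
    # 60-nt transcript: 5' UTR 1-15, CDS 16-35, 3' UTR 36-60
    seq = "ACGUACGUACGUACGAUGGCCAAAGGGCCCUUUAAGCUAGCUAGCUAAGGCCAAUUGGCC"
    return TranscriptRecord(
        transcript_id="NM_TOY1",
        gene="TOY1",
        sequence=seq,
        utr5=(1, 15),
        utr3=(36, 60),
    )


@pytest.fixture()
def toy_snv(toy_transcript):
    pos = 45
    return SnvRecord(
        "NM_TOY1", pos, toy_transcript.base(pos), "G" if toy_transcript.base(pos) != "G" else "A",
        utr_label="3",
    )
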