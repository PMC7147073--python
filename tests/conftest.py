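import numpy as np
import pytest

from gonadiso import synthetic as syn
from gonadiso.core_io import Transcript, TranscriptSet


@pytest.fixture(scope="session")
def design():
    return syn.default_design()


@pytest.fixture(scope="session")
def family_set():
    """Parents + one deletion isoform each + near-duplicates, with truth."""
    parents, truth = syn.generate_transcript_set(8, (1200, 3000), seed=7)
    ts, truth = syn.plant_isoforms(parents, truth, gap_range=(120, 400),
                                   flank_min=150, seed=1, sub_rate=0.005)
    ts, truth = syn.plant_duplicates(ts, truth, q=0.995, seed=2)
    return ts, truth


@pytest.fixture(scope="session")
def coding_noncoding():
    return syn.generate_coding_noncoding(100, orf_aa_range=(300, 500), seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_transcript(rng, tid: str, length: int) -> Transcript:
    return Transcript(tid, "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)]))


@pytest.fixture
def make_transcript(rng):
    def _make(tid="t", length=1200):
        return random_transcript(rng, tid, length)
    return _make
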