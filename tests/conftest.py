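import numpy as np
import pytest

from ontoweave.corpus import TokenizerConfig, tokenize
from ontoweave.ontology import Terminology


@pytest.fixture
def note_doc():
    """A small clinical-note-like document with sections and a timestamp."""
    text = (
        "PAST MEDICAL HISTORY:\n"
        "Diabetes mellitus diagnosed 2019-01-02. Duchenne muscular dystrophy (DMD) noted.\n\n"
        "ASSESSMENT:\n"
        "Patient denies fever today. DMD stable. Follow up in 3 days."
    )
    return tokenize(
        text,
        TokenizerConfig(section_headers=[r"past medical history:", r"assessment:"]),
        doc_id="note1",
        timestamp="2020-03-01T00:00:00",
    )


@pytest.fixture
def disease_terminology():
    k = 1
    vecs = {
        "lung": [1.0, 0.0],  # anatomy -> negative class
        "lung cancer": [0.0, 1.0],
        "diabetes mellitus": [0.0, 1.0],
        "duchenne muscular dystrophy": [0.0, 1.0],
        "fever": [0.0, 1.0],
        "tylenol": [0.0, 1.0],
        "acetaminophen": [0.0, 1.0],
    }
    return Terminology(
        name="disease_demo",
        terms={t: np.array(v) for t, v in vecs.items()},
        k=k,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
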