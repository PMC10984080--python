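import numpy as np
import pytest

from psychnote.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def paper_like_corpus():
    """A small cohort-emulating corpus shared across tests (seeded)."""
    return generate_corpus(SynthConfig.paper_like(n_notes=300, seed=1234))


@pytest.fixture(scope="session")
def short_note_corpus():
    """Short labelled notes (single-tier emission) for quick model fits."""
    return generate_corpus(SynthConfig.poisson_recovery(n_notes=400, seed=77))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
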