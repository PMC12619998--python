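import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def point_mass_motif():
    from tomtomlite.motifs import Motif

    return Motif(name="pm", matrix=np.array([[1.0], [0.0], [0.0], [0.0]]))
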