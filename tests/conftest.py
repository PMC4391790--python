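import numpy as np
import pytest

from kolfold.msa import Msa
from kolfold.synthetic import ConservationProfile, synth_globule_trace, synth_msa


@pytest.fixture
def tiny_msa() -> Msa:
    """3 sequences x 5 columns covering conserved, diverse and gapped columns."""
    return Msa(
        ids=("a", "b", "c"),
        rows=("ACDEF", "ACDKF", "AC-EF"),
    )


@pytest.fixture
def mixed_msa() -> Msa:
    """Synthetic MSA with alternating conserved (k=1) and diverse (k=20) columns."""
    profile = ConservationProfile(k=(1, 20) * 10)
    return synth_msa(20, 600, profile, seed=11)


@pytest.fixture
def globule():
    return synth_globule_trace(40, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
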