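import pytest

from extorf.synthetic_data import make_cpc1_like


@pytest.fixture(scope="session")
def cpc1_like():
    """Synthetic stand-in for the cpc-1 worked example: (Transcript, truth)."""
    return make_cpc1_like(seed=1729)
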