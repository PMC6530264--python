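import pytest

from bottlesim import fixtures


@pytest.fixture(scope="session")
def miniature():
    """The 55 mL reference miniature bottle (deterministic)."""
    return fixtures.miniature_bottle()
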