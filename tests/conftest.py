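import logging

import pytest

from utrext.simulate import make_evidence, make_genome


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # repair/clip paths log warnings by design; keep test output readable
    logging.getLogger("utrext").setLevel(logging.WARNING)
    yield


@pytest.fixture(scope="session")
def clean_world():
    """A 30-gene noise-free world shared by read-only tests."""
    return make_genome(n_genes=30, seed=42)


@pytest.fixture(scope="session")
def clean_evidence(clean_world):
    return make_evidence(clean_world.original, clean_world.truncated, seed=42)
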