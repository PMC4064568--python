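import pytest

from pathwaycv import load_tables


@pytest.fixture(scope="session")
def tables():
    return load_tables()
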