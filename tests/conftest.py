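import pytest

from mitocohort.mito_map import load_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()
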