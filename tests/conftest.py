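import pytest

from adept import default_lexicon, default_rules


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def rules():
    return default_rules()
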