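import pytest

from predspeech.lexicon import (
    build_feature_scheme,
    default_lexicon,
    default_segment_table,
    word_feature_matrix,
)


@pytest.fixture(scope="session")
def scheme():
    return build_feature_scheme()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def segment_table():
    return default_segment_table()


@pytest.fixture(scope="session")
def W(lexicon, scheme, segment_table):
    return word_feature_matrix(lexicon, scheme, segment_table)
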