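import pytest
from hypothesis import settings

from innlint import load_default_infix_table, load_default_lexicon

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def infix_table():
    return load_default_infix_table()


#: The nine unusually long names (over 20 characters) published before 1962,
#: used as a fixed input corpus in several length-statistics tests.
LONG_NAMES = [
    "sulfachlorpyridazine",
    "succinylsulfathiazole",
    "methyldihydromorphine",
    "phthalylsulfathiazole",
    "ethylmethylthiambutene",
    "phthalylsulfamethizole",
    "sulfamethoxypyridazine",
    "diiodohydroxyquinoline",
    "phenoxymethylpenicillin",
]


@pytest.fixture(scope="session")
def long_name_corpus():
    from innlint import make_corpus

    return make_corpus((n, 1955) for n in LONG_NAMES)
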