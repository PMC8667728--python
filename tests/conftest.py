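import pytest

from cladedef import load_corpus, read_newick
from cladedef.resolver import ResolveOptions


@pytest.fixture(scope="session")
def corpus():
    return load_corpus("packaged")


@pytest.fixture(scope="session")
def default_options(corpus):
    return ResolveOptions(aliases=corpus.alias_map)


@pytest.fixture()
def five_tip_tree():
    # ((A a, B b), (C c, (D d, E e)))
    return read_newick("((A_a,B_b),(C_c,(D_d,E_e)));")
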