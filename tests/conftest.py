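import random

import pytest

from sempar.fixtures import FixtureSpec, figure1_fixture, random_corpus, random_dag
from sempar.ontology import OntologyGraph

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: T:root
name: root
namespace: toy

[Term]
id: T:mid
name: mid
namespace: toy
is_a: T:root ! root

[Term]
id: T:leaf
name: leaf
namespace: toy
is_a: T:mid ! mid
"""


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return str(path)


@pytest.fixture
def chain_graph():
    """leaf -is_a-> mid -is_a-> root."""
    return OntologyGraph.build(
        [("T:leaf", "T:mid", "is_a"), ("T:mid", "T:root", "is_a")]
    )


@pytest.fixture
def figure1():
    return figure1_fixture()


@pytest.fixture(params=range(5))
def seeded_dag(request):
    spec = FixtureSpec(n_terms=25, max_parents=3, n_genes=8, seed=request.param)
    return random_dag(spec), spec


@pytest.fixture
def seeded_corpus(seeded_dag):
    g, spec = seeded_dag
    return g, random_corpus(g, spec)


def random_subset(g: OntologyGraph, rng: random.Random, *, allow_empty: bool = False):
    terms = sorted(g.terms)
    lo = 0 if allow_empty else 1
    k = rng.randint(lo, min(4, len(terms)))
    return set(rng.sample(terms, k))
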