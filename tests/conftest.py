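import random

import pytest

from wgt import LabeledDigraph, parse_dot


def random_labeled_digraph(rng: random.Random, n: int, e: int, sigma: int) -> LabeledDigraph:
    """Uniform random labeled digraph (not biased toward Wheeler)."""
    nodes = [f"n{i}" for i in range(n)]
    labels = [chr(ord("A") + i) for i in range(sigma)]
    edges = set()
    attempts = 0
    while len(edges) < e and attempts < 50 * e:
        edges.add((rng.choice(nodes), rng.choice(nodes), rng.choice(labels)))
        attempts += 1
    return LabeledDigraph(nodes=set(nodes), edges=sorted(edges))


def random_bijection(rng: random.Random, g: LabeledDigraph):
    nodes = sorted(g.nodes)
    ranks = list(range(1, len(nodes) + 1))
    rng.shuffle(ranks)
    return dict(zip(nodes, ranks))


@pytest.fixture
def path_graph():
    """v1 -A-> v2 -A-> v3."""
    return parse_dot('digraph{v1->v2[label="A"]; v2->v3[label="A"]}')


@pytest.fixture
def fork_two_labels():
    """r -A-> x, r -B-> y."""
    return parse_dot('digraph{r->x[label="A"]; r->y[label="B"]}')


@pytest.fixture
def fork_same_label():
    """r -A-> x, r -A-> y (a genuine tie)."""
    return parse_dot('digraph{r->x[label="A"]; r->y[label="A"]}')


@pytest.fixture
def two_cycle():
    """a <-A-> b: non-Wheeler without any label conflict."""
    return parse_dot('digraph{a->b[label="A"]; b->a[label="A"]}')


@pytest.fixture
def label_conflict():
    """Two distinctly labeled edges into c: the canonical conflict."""
    return parse_dot('digraph{a->c[label="A"]; b->c[label="B"]}')
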