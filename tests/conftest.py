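import random

import networkx as nx
import pytest

from qualnet.casestudy import (
    CaseStudyConfig,
    dnmt1_network,
    run_dnmt1_analysis,
    working_model,
)
from qualnet.ctl import And, Atom, Bool, LabeledDigraph, Not, Or, Unary, Until
from qualnet.dynamics import build_state_graph


@pytest.fixture(scope="session")
def dnmt1():
    return dnmt1_network()


@pytest.fixture(scope="session")
def case_report():
    return run_dnmt1_analysis(CaseStudyConfig())


@pytest.fixture(scope="session")
def selected_model():
    """(id, brn, table) of the case study's working model."""
    return working_model()


@pytest.fixture(scope="session")
def selected_graph(selected_model):
    _, brn, table = selected_model
    return build_state_graph(brn, table, add_stable_selfloops=True)


# ---------------------------------------------------------------------------
# Random Kripke structures and CTL formulas for the oracle suites
# ---------------------------------------------------------------------------

def random_kripke(rng: random.Random, max_states: int = 12) -> LabeledDigraph:
    """A random total digraph with a single observed variable V in 0..2."""
    n = rng.randint(2, max_states)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if rng.random() < 0.25:
                g.add_edge(u, v)
    for u in range(n):  # totality
        if g.out_degree(u) == 0:
            g.add_edge(u, rng.randrange(n))
    valuation = {s: {"V": rng.randint(0, 2)} for s in range(n)}
    return LabeledDigraph(g, valuation)


def random_formula(rng: random.Random, depth: int = 4):
    if depth == 0 or rng.random() < 0.3:
        r = rng.random()
        if r < 0.1:
            return Bool(rng.random() < 0.5)
        op = rng.choice(["=", "<=", ">=", "<", ">", "!="])
        return Atom("V", op, rng.randint(0, 2))
    kind = rng.choice(
        ["not", "and", "or", "EX", "AX", "EF", "AF", "EG", "AG", "EU", "AU"]
    )
    if kind == "not":
        return Not(random_formula(rng, depth - 1))
    if kind == "and":
        return And(random_formula(rng, depth - 1), random_formula(rng, depth - 1))
    if kind == "or":
        return Or(random_formula(rng, depth - 1), random_formula(rng, depth - 1))
    if kind in ("EU", "AU"):
        return Until(
            kind[0], random_formula(rng, depth - 1), random_formula(rng, depth - 1)
        )
    return Unary(kind, random_formula(rng, depth - 1))


def random_digraph(rng: random.Random, max_nodes: int = 10) -> nx.DiGraph:
    n = rng.randint(2, max_nodes)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < 0.3:
                g.add_edge(u, v)
    return g
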