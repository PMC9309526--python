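"""Seeded generators: random networks, parameter tables, observation sets,
and synthetic compound-screen tables.

Every generator is a pure function of its seed and parameters, so the
whole pipeline is testable without downloads. The compound generator
emulates the shape of a small-molecule inhibitor screen: IC50 potencies
spanning 0.01-1,600 uM drawn from a two-component mixture on the log10
scale straddling the 10 uM activity threshold, and ten numeric descriptor
columns whose class-conditional means are separated by a configurable
amount.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ctl import And, Atom, CTLFormula, Unary
from .dynamics import StateGraph
from .network import BRN, GeneVariable, Interaction, ParameterTable, resource_sets

__all__ = [
    "random_brn",
    "random_table",
    "ObservationSet",
    "observations_from_graph",
    "all_transition_observations",
    "synthetic_compound_table",
]

#: IC50 range of the emulated inhibitor screen, in micromolar.
IC50_RANGE_UM = (0.01, 1600.0)


def random_brn(
    seed: int,
    n_vars: int = 4,
    edge_density: float = 0.4,
    max_level: int = 1,
) -> BRN:
    """A reproducible random network.

    Each ordered variable pair (self-pairs included) carries an edge with
    probability ``edge_density``; thresholds are uniform over the source's
    valid range and signs uniform over {+, -}. Every variable gets the
    domain ``{0..max_level}``.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"G{i + 1}" for i in range(n_vars)]
    variables = [GeneVariable(n, max_level) for n in names]
    interactions = []
    for src in names:
        for dst in names:
            if rng.random() < edge_density:
                interactions.append(
                    Interaction(
                        src,
                        dst,
                        "+" if rng.random() < 0.5 else "-",
                        int(rng.integers(1, max_level + 1)),
                    )
                )
    return BRN(variables, interactions)


def random_table(brn: BRN, seed: int, snoussi: bool = False) -> ParameterTable:
    """A complete random parameter table for ``brn``.

    With ``snoussi=True`` the table is made monotone by construction: K
    values are sampled independently and then closed upward, so that
    adding a resource never lowers the focal level.
    """
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, frozenset[str]], int] = {}
    for v in brn.variables:
        subsets = resource_sets(brn, v.name)
        ks = [int(rng.integers(0, v.max_level + 1)) for _ in subsets]
        if snoussi:
            # upward closure over the subset lattice (canonical order is
            # size-sorted, so smaller sets are processed first)
            for i, a in enumerate(subsets):
                for j, b in enumerate(subsets):
                    if a < b and ks[j] < ks[i]:
                        ks[j] = ks[i]
        for sub, k in zip(subsets, ks):
            entries[(v.name, sub)] = k
    return ParameterTable(entries)


class ObservationSet:
    """CTL facts true of a state graph by construction."""

    def __init__(self, formulas: Sequence[CTLFormula], seed: Optional[int] = None):
        self.formulas = list(formulas)
        self.seed = seed

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self):
        return iter(self.formulas)


def _characterize(graph: StateGraph, state) -> CTLFormula:
    """Conjunction of atoms pinning every coordinate of ``state``."""
    assert graph.brn is not None
    order = graph.brn.state_order
    node: CTLFormula = Atom(order[0], "=", state[0])
    for name, lvl in zip(order[1:], state[1:]):
        node = And(node, Atom(name, "=", lvl))
    return node


def _transition_fact(graph: StateGraph, u, v) -> CTLFormula:
    from .ctl import Implies

    return Implies(_characterize(graph, u), Unary("EX", _characterize(graph, v)))


def all_transition_observations(graph: StateGraph) -> ObservationSet:
    """One EX fact per edge (self-loops included): the full transition list."""
    facts = [_transition_fact(graph, u, v) for u, v in graph.edges]
    return ObservationSet(facts)


def observations_from_graph(
    graph: StateGraph, seed: int, n_facts: int
) -> ObservationSet:
    """Sample ``n_facts`` transition facts true of ``graph``.

    Each fact characterizes a source state and asserts the existence of
    the observed successor (``state -> EX successor``); stable states
    contribute their self-loop. Raises when more facts are requested than
    the graph has edges.
    """
    edges = graph.edges
    if n_facts > len(edges):
        raise ValueError(f"requested {n_facts} facts but only {len(edges)} available")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(edges), size=n_facts, replace=False))
    facts = [_transition_fact(graph, *edges[i]) for i in chosen]
    return ObservationSet(facts, seed)


# ---------------------------------------------------------------------------
# Compound-screen emulation
# ---------------------------------------------------------------------------

N_DESCRIPTORS = 10


def synthetic_compound_table(
    seed: int,
    n: int = 242,
    class_separation: float = 1.5,
    p_active: float = 0.68,
) -> pd.DataFrame:
    """Emulate a compound inhibition screen as a DataFrame.

    Columns: ``id``, ``mw`` (Da), ``ic50_um``, descriptors ``d01..d10``.
    IC50 values are drawn from a two-component normal mixture on the log10
    scale (actives centered near 1 uM, least-actives near 150 uM), clipped
    to the 0.01-1,600 uM range, so the histogram is bimodal around the
    10 uM activity threshold. Descriptor class-conditional means differ by
    ``class_separation`` (full shift on d01, attenuated on the rest).
    Defaults give roughly the active/least-active balance of a curated
    DNMT1 inhibitor set (about 68% active).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    active = rng.random(n) < p_active
    log_ic50 = np.where(
        active,
        rng.normal(0.0, 0.8, size=n),     # ~1 uM center
        rng.normal(2.2, 0.5, size=n),     # ~150 uM center
    )
    lo, hi = IC50_RANGE_UM
    ic50 = np.clip(10.0 ** log_ic50, lo, hi)
    mw = np.clip(rng.normal(420.0, 90.0, size=n), 210.0, 900.0)
    weights = np.array([1.0] + [0.35] * (N_DESCRIPTORS - 1))
    data = {
        "id": [f"CPD{i + 1:04d}" for i in range(n)],
        "mw": np.round(mw, 1),
        "ic50_um": ic50,
    }
    for k in range(N_DESCRIPTORS):
        shift = class_separation * weights[k]
        data[f"d{k + 1:02d}"] = rng.normal(np.where(active, shift, 0.0), 1.0)
    return pd.DataFrame(data)
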