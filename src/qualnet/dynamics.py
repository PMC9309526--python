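"""Asynchronous unitary dynamics over a parameterized BRN.

In each qualitative state every variable has a *focal level*
``K_v(resources_v(state))``. A variable whose current level differs from
its focal level may move **one unit** toward it; each such variable yields
its own transition (asynchronous, non-deterministic update). A state where
every variable sits at its focal level is stable; stable states optionally
carry self-loops so the transition relation is total (a Kripke structure),
which the CTL checker requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .network import BRN, ParameterTable, resource_sets, resources

__all__ = [
    "StateSpace",
    "Transition",
    "StateGraph",
    "focal_levels",
    "successors",
    "build_state_graph",
    "stable_states",
    "induced_slice",
    "StateSpaceGuardError",
]

State = tuple[int, ...]


class StateSpaceGuardError(RuntimeError):
    """Raised when a state space exceeds the configured size cap."""


@dataclass(frozen=True)
class Transition:
    """One asynchronous step: exactly one coordinate moves by one unit.

    Self-loops on stable states are encoded with ``changed_variable=None``
    and ``direction=0``.
    """

    from_state: State
    to_state: State
    changed_variable: Optional[str]
    direction: int

    def __post_init__(self) -> None:
        if self.changed_variable is None:
            if self.from_state != self.to_state or self.direction != 0:
                raise ValueError("self-loop transition must not change the state")
            return
        diffs = [
            (i, b - a) for i, (a, b) in enumerate(zip(self.from_state, self.to_state))
            if a != b
        ]
        if len(diffs) != 1 or abs(diffs[0][1]) != 1 or diffs[0][1] != self.direction:
            raise ValueError(
                "transition must change exactly one coordinate by one unit"
            )


class StateSpace:
    """Precomputed product state space of a BRN.

    Caches, per state and per variable, the realized resource set (which
    depends on the topology only, not on the parameter table), so that
    state graphs for many candidate tables can be built cheaply.
    """

    def __init__(self, brn: BRN, max_states: int = 1_000_000) -> None:
        self.brn = brn
        n = brn.n_states()
        if n > max_states:
            raise StateSpaceGuardError(
                f"state space has {n} states, exceeding the cap of {max_states}"
            )
        maxes = [brn.variable(name).max_level for name in brn.state_order]
        states: list[State] = []

        def rec(prefix: list[int], i: int) -> None:
            if i == len(maxes):
                states.append(tuple(prefix))
                return
            for lvl in range(maxes[i] + 1):
                rec(prefix + [lvl], i + 1)

        rec([], 0)
        self.states: tuple[State, ...] = tuple(states)
        self.index: dict[State, int] = {s: i for i, s in enumerate(states)}
        # per-variable canonical subset list and lookup
        self.subsets: dict[str, list[frozenset[str]]] = {
            name: resource_sets(brn, name) for name in brn.state_order
        }
        self._subset_pos = {
            name: {sub: i for i, sub in enumerate(subs)}
            for name, subs in self.subsets.items()
        }
        # resource subset index per (state, variable)
        self.resource_index: list[tuple[int, ...]] = []
        for s in self.states:
            row = tuple(
                self._subset_pos[name][resources(brn, s, name)]
                for name in brn.state_order
            )
            self.resource_index.append(row)

    def table_vectors(self, table: ParameterTable) -> list[tuple[int, ...]]:
        """Per-variable K vectors aligned with the canonical subset order."""
        return [
            tuple(table.k(name, sub) for sub in self.subsets[name])
            for name in self.brn.state_order
        ]


def focal_levels(
    brn: BRN, table: ParameterTable, state: Sequence[int]
) -> dict[str, int]:
    """Focal level of each variable in ``state``: ``K_v(resources_v(state))``."""
    state = brn.check_state(state)
    return {
        name: table.k(name, resources(brn, state, name)) for name in brn.state_order
    }


def successors(
    brn: BRN, table: ParameterTable, state: Sequence[int]
) -> list[Transition]:
    """Asynchronous unitary successors of ``state``; empty iff stable."""
    state = brn.check_state(state)
    focal = focal_levels(brn, table, state)
    out: list[Transition] = []
    for i, name in enumerate(brn.state_order):
        cur = state[i]
        target = focal[name]
        if target == cur:
            continue
        step = 1 if target > cur else -1
        nxt = state[:i] + (cur + step,) + state[i + 1:]
        out.append(Transition(state, nxt, name, step))
    return out


class StateGraph:
    """Asynchronous state transition graph of a parameterized BRN.

    Wraps a :class:`networkx.DiGraph` whose nodes are state tuples. Edge
    attributes record the changed variable and direction; stable-state
    self-loops (when enabled) have ``variable=None``.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        brn: Optional[BRN] = None,
        table: Optional[ParameterTable] = None,
        stable_selfloops: bool = True,
    ) -> None:
        self.graph = graph
        self.brn = brn
        self.table = table
        self.stable_selfloops = stable_selfloops

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> list[State]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[State, State]]:
        return sorted(self.graph.edges)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self, count_selfloops: bool = True) -> int:
        if count_selfloops:
            return self.graph.number_of_edges()
        return sum(1 for u, v in self.graph.edges if u != v)

    def successor_states(self, state: State) -> list[State]:
        return sorted(self.graph.successors(state))

    def transitions(self) -> list[Transition]:
        out = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            out.append(
                Transition(u, v, data.get("variable"), data.get("direction", 0))
            )
        return out

    def state_value(self, state: State, var: str) -> int:
        """Level of ``var`` in ``state`` (used by the CTL checker's atoms)."""
        if self.brn is None:
            raise ValueError("state graph carries no BRN; atoms cannot be evaluated")
        return self.brn.level_in_state(state, var)

    # -- exports -----------------------------------------------------------
    @staticmethod
    def _label(state: State) -> str:
        return ",".join(str(x) for x in state)

    def to_graphml(self, path: str) -> None:
        g = nx.relabel_nodes(self.graph, {s: self._label(s) for s in self.graph.nodes})
        for _, _, data in g.edges(data=True):
            if data.get("variable") is None:
                data["variable"] = ""
        nx.write_graphml(g, path)

    def to_dot(self) -> str:
        lines = ["digraph stategraph {"]
        for s in self.nodes:
            lines.append(f'  "{self._label(s)}";')
        for u, v in self.edges:
            lines.append(f'  "{self._label(u)}" -> "{self._label(v)}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_edge_csv(self) -> str:
        lines = ["from,to,variable,direction"]
        for u, v, data in sorted(self.graph.edges(data=True)):
            var = data.get("variable") or ""
            lines.append(
                f"{self._label(u)},{self._label(v)},{var},{data.get('direction', 0)}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_csv(cls, text: str) -> "StateGraph":
        """Analysis-only import: rebuilds the digraph, without provenance."""
        g = nx.DiGraph()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for line in lines[1:]:
            parts = line.split(",")
            # state labels are comma-joined, so split from both ends
            n = (len(parts) - 2) // 2
            u = tuple(int(x) for x in parts[:n])
            v = tuple(int(x) for x in parts[n:2 * n])
            var = parts[2 * n] or None
            direction = int(parts[2 * n + 1])
            g.add_edge(u, v, variable=var, direction=direction)
        return cls(g, stable_selfloops=True)


def build_state_graph(
    brn: BRN,
    table: ParameterTable,
    restrict_reachable_from: Optional[Iterable[Sequence[int]]] = None,
    add_stable_selfloops: bool = True,
    max_states: int = 1_000_000,
    space: Optional[StateSpace] = None,
) -> StateGraph:
    """Build the asynchronous state transition graph of ``(brn, table)``.

    Parameters
    ----------
    restrict_reachable_from:
        Optional seed states; when given, the graph is the vertex-induced
        subgraph on states reachable from the seed set (the seed states
        themselves included).
    add_stable_selfloops:
        Give stable states a self-loop so the relation is total.
    space:
        Optional precomputed :class:`StateSpace` to amortize resource
        lookups across many tables of the same BRN.
    """
    if space is None:
        space = StateSpace(brn, max_states=max_states)
    vectors = space.table_vectors(table)
    order = brn.state_order
    maxes = [brn.variable(name).max_level for name in order]

    def succ_of(idx: int) -> list[tuple[State, str, int]]:
        s = space.states[idx]
        row = space.resource_index[idx]
        out = []
        for i, name in enumerate(order):
            target = vectors[i][row[i]]
            cur = s[i]
            if target == cur:
                continue
            step = 1 if target > cur else -1
            nxt = s[:i] + (cur + step,) + s[i + 1:]
            out.append((nxt, name, step))
        return out

    g = nx.DiGraph()
    if restrict_reachable_from is None:
        node_indices = range(len(space.states))
        for idx in node_indices:
            g.add_node(space.states[idx])
        for idx in node_indices:
            s = space.states[idx]
            for nxt, name, step in succ_of(idx):
                g.add_edge(s, nxt, variable=name, direction=step)
    else:
        seeds = [brn.check_state(s) for s in restrict_reachable_from]
        stack = [space.index[s] for s in seeds]
        seen = set(stack)
        for s in seeds:
            g.add_node(s)
        while stack:
            idx = stack.pop()
            s = space.states[idx]
            for nxt, name, step in succ_of(idx):
                g.add_edge(s, nxt, variable=name, direction=step)
                j = space.index[nxt]
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
    if add_stable_selfloops:
        for s in list(g.nodes):
            if g.out_degree(s) == 0:
                g.add_edge(s, s, variable=None, direction=0)
    _ = maxes  # domain bounds already enforced by check_state / StateSpace
    return StateGraph(g, brn=brn, table=table, stable_selfloops=add_stable_selfloops)


def induced_slice(
    graph: StateGraph, bounds: Mapping[str, tuple[int, int]]
) -> StateGraph:
    """Vertex-induced subgraph on states whose levels fall within ``bounds``.

    ``bounds`` maps variable names to inclusive ``(lo, hi)`` level windows;
    unmentioned variables are unconstrained. Useful for analyzing the slice
    of the dynamics a figure or report displays. The slice need not be
    closed under transitions, so its relation may be non-total.
    """
    if graph.brn is None:
        raise ValueError("level slicing requires a graph with BRN provenance")
    idx = {name: graph.brn.state_index(name) for name in bounds}
    for name in bounds:
        graph.brn.variable(name)

    def keep(state: State) -> bool:
        return all(lo <= state[idx[n]] <= hi for n, (lo, hi) in bounds.items())

    sub = graph.graph.subgraph([s for s in graph.graph.nodes if keep(s)]).copy()
    return StateGraph(sub, brn=graph.brn, table=graph.table,
                      stable_selfloops=graph.stable_selfloops)


def stable_states(graph: StateGraph) -> list[State]:
    """States with no outgoing move (only the self-loop, when enabled)."""
    out = []
    for s in graph.nodes:
        succ = set(graph.graph.successors(s))
        if not succ or succ == {s}:
            out.append(s)
    return out
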