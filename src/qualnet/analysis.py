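"""Centrality, attractor, trajectory, and bifurcation analysis of state graphs.

The betweenness centrality of a qualitative state measures how many
shortest inter-state trajectories pass through it; in a state-transition
graph the most central states are the ones the system traverses most
often, which makes them candidate checkpoints of the modeled biology.
Betweenness here is *raw* (unnormalized), directed, with self-loops
ignored, and accumulated with exact rational arithmetic so that tie-heavy
tiny graphs do not suffer float drift.

Attractors are the terminal strongly connected components of the graph:
once entered, never left. In models where several biological regimes
(for example a pathological loop and a homeostatic cycle) cohabit a single
terminal component, an :class:`AttractorReport` can instead be built from
user-designated marker states, and bifurcation analysis then counts which
designated regimes remain reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import networkx as nx

__all__ = [
    "betweenness",
    "AttractorReport",
    "attractors",
    "find_path",
    "bifurcation_states",
    "TrajectoryReport",
    "verify_trajectory",
    "path_through",
    "centrality_to_csv",
]


def _digraph(graph) -> nx.DiGraph:
    """Accept a StateGraph (or any wrapper) or a bare networkx DiGraph."""
    if isinstance(graph, nx.DiGraph):
        return graph
    return graph.graph


def betweenness(graph) -> dict:
    """Raw directed betweenness centrality of every node.

    For each ordered pair ``(s, t)`` with ``s != t``, each interior vertex
    ``v`` of the shortest ``s -> t`` paths accumulates the fraction of
    those paths passing through it. Brandes' dependency accumulation is
    used with :class:`fractions.Fraction` arithmetic; the returned values
    are exact non-negative rationals.
    """
    g = _digraph(graph)
    nodes = sorted(g.nodes)
    succ = {v: sorted(u for u in g.successors(v) if u != v) for v in nodes}
    score: dict = {v: Fraction(0) for v in nodes}
    for s in nodes:
        # BFS shortest-path DAG from s
        dist = {s: 0}
        sigma = {v: 0 for v in nodes}
        sigma[s] = 1
        parents: dict = {v: [] for v in nodes}
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in succ[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                        order.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        parents[w].append(v)
            frontier = nxt
        delta = {v: Fraction(0) for v in order}
        for w in reversed(order):
            for v in parents[w]:
                delta[v] += Fraction(sigma[v], sigma[w]) * (1 + delta[w])
            if w is not s:
                score[w] += delta[w]
    return score


def centrality_to_csv(cmap: dict) -> str:
    lines = ["state,betweenness"]
    for state in sorted(cmap):
        label = ",".join(str(x) for x in state) if isinstance(state, tuple) else str(state)
        lines.append(f"\"{label}\",{float(cmap[state])}")
    return "\n".join(lines) + "\n"


@dataclass
class AttractorReport:
    """A list of disjoint attractor state sets with optional labels.

    ``designated`` is False when the attractors are the graph's terminal
    strongly connected components (no edge leaves them), and True when
    they are user-designated marker regimes used only to classify
    trajectories.
    """

    attractors: list[frozenset]
    labels: dict[int, str] = field(default_factory=dict)
    designated: bool = False

    def __post_init__(self) -> None:
        seen: set = set()
        for a in self.attractors:
            if a & seen:
                raise ValueError("attractors must be pairwise disjoint")
            seen |= a

    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for a in self.attractors:
            out |= a
        return out

    @classmethod
    def from_markers(cls, graph, markers: dict) -> "AttractorReport":
        """Designate regimes by marker states (``label -> state``)."""
        g = _digraph(graph)
        atts = []
        labels = {}
        for i, (label, state) in enumerate(sorted(markers.items())):
            state = tuple(state)
            if state not in g:
                raise ValueError(f"marker state {state} is not a node of the graph")
            atts.append(frozenset([state]))
            labels[i] = label
        return cls(atts, labels, designated=True)


def attractors(graph) -> AttractorReport:
    """Terminal strongly connected components of the graph.

    A singleton terminal SCC is a stable state. No edge leaves an
    attractor (asserted before returning).
    """
    g = _digraph(graph)
    comps = list(nx.strongly_connected_components(g))
    out = []
    for comp in comps:
        if all(w in comp for v in comp for w in g.successors(v)):
            out.append(frozenset(comp))
    out.sort(key=lambda c: sorted(c)[0])
    for a in out:  # closure sanity check
        assert all(w in a for v in a for w in g.successors(v))
    return AttractorReport(out)


def find_path(graph, from_state, to_state) -> Optional[list]:
    """A shortest path between two states, or ``None`` when unreachable.

    A path from a state to itself is the empty journey ``[from_state]``.
    """
    g = _digraph(graph)
    from_state = tuple(from_state) if isinstance(from_state, (list, tuple)) else from_state
    to_state = tuple(to_state) if isinstance(to_state, (list, tuple)) else to_state
    for s in (from_state, to_state):
        if s not in g:
            raise ValueError(f"state {s} is not a node of the graph")
    try:
        return nx.shortest_path(g, from_state, to_state)
    except nx.NetworkXNoPath:
        return None


def path_through(graph, from_state, via_state, to_state) -> Optional[list]:
    """A (not necessarily shortest) path ``from -> via -> to``; None if absent."""
    first = find_path(graph, from_state, via_state)
    if first is None:
        return None
    second = find_path(graph, via_state, to_state)
    if second is None:
        return None
    return first + second[1:]


def bifurcation_states(graph, attractor_report: AttractorReport) -> frozenset:
    """States from which at least two of the report's attractors are
    reachable, excluding states inside any attractor.

    With a terminal-SCC report this is the classical notion of a state
    whose future is still undecided between attractors; with a
    marker-designated report it classifies states that can still evolve
    toward at least two of the designated regimes.
    """
    g = _digraph(graph)
    counts: dict = {v: 0 for v in g.nodes}
    for a in attractor_report.attractors:
        basin: set = set(a)
        for member in a:
            basin |= nx.ancestors(g, member)
            if not attractor_report.designated:
                break  # SCC members share their ancestor set
        for v in basin:
            counts[v] += 1
    union = attractor_report.union()
    return frozenset(v for v, c in counts.items() if c >= 2 and v not in union)


@dataclass
class TrajectoryReport:
    """Edge-by-edge verification of a printed state sequence."""

    sequence: list
    edge_present: list[bool]
    unknown_states: list[int]  # positions of states absent from the graph
    first_failure: Optional[int] = None

    @property
    def ok(self) -> bool:
        return not self.unknown_states and all(self.edge_present)


def verify_trajectory(graph, sequence: Sequence) -> TrajectoryReport:
    """Check that each consecutive pair of ``sequence`` is a graph edge."""
    g = _digraph(graph)
    seq = [tuple(s) if isinstance(s, (list, tuple)) else s for s in sequence]
    unknown = [i for i, s in enumerate(seq) if s not in g]
    flags: list[bool] = []
    first_failure = None
    for i in range(len(seq) - 1):
        present = (
            i not in unknown
            and (i + 1) not in unknown
            and g.has_edge(seq[i], seq[i + 1])
        )
        flags.append(present)
        if not present and first_failure is None:
            first_failure = i
    return TrajectoryReport(seq, flags, unknown, first_failure)
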