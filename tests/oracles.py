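"""Independent reference implementations used only to cross-check results.

These deliberately use different formulations than the package: CTL via
graph-closure computations (descendants / cycle reachability on induced
subgraphs) instead of fixed-point labeling, betweenness via explicit
shortest-path enumeration instead of dependency accumulation, attractors
via an exhaustive no-escaping-edge scan over SCCs.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx

from qualnet.ctl import And, Atom, Bool, Implies, Not, Or, Unary, Until


# ---------------------------------------------------------------------------
# CTL path semantics via graph closures
# ---------------------------------------------------------------------------

def _cycle_reach(h: nx.DiGraph) -> set:
    """Nodes of ``h`` from which a cycle of ``h`` is reachable."""
    on_cycle = set()
    for comp in nx.strongly_connected_components(h):
        if len(comp) > 1 or any(h.has_edge(v, v) for v in comp):
            on_cycle |= comp
    out = set(on_cycle)
    for v in on_cycle:
        out |= nx.ancestors(h, v)
    return out


def _reach_through(g: nx.DiGraph, hold: set, target: set) -> set:
    """States with a path into ``target`` whose prefix stays in ``hold``."""
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    for u, v in g.edges:
        if u in hold:
            h.add_edge(u, v)
    out = set(target)
    rev = h.reverse(copy=False)
    for t in target:
        out |= nx.descendants(rev, t)
    return {s for s in out if s in target or s in hold}


def oracle_sat(graph, formula) -> set:
    """Satisfaction set computed by closure-based path semantics."""
    g = graph.graph
    nodes = set(g.nodes)

    def ev(f) -> set:
        if isinstance(f, Bool):
            return set(nodes) if f.value else set()
        if isinstance(f, Atom):
            ops = {
                "=": lambda a, b: a == b,
                "!=": lambda a, b: a != b,
                "<=": lambda a, b: a <= b,
                ">=": lambda a, b: a >= b,
                "<": lambda a, b: a < b,
                ">": lambda a, b: a > b,
            }
            return {
                s for s in nodes
                if ops[f.op](graph.state_value(s, f.var), f.const)
            }
        if isinstance(f, Not):
            return nodes - ev(f.child)
        if isinstance(f, And):
            return ev(f.left) & ev(f.right)
        if isinstance(f, Or):
            return ev(f.left) | ev(f.right)
        if isinstance(f, Implies):
            return (nodes - ev(f.left)) | ev(f.right)
        if isinstance(f, Unary):
            child = ev(f.child)
            if f.op == "EX":
                return {s for s in nodes if set(g.successors(s)) & child}
            if f.op == "AX":
                return {s for s in nodes if set(g.successors(s)) <= child}
            if f.op == "EF":
                return {s for s in nodes if s in child or nx.descendants(g, s) & child}
            if f.op == "AG":
                bad = nodes - child
                return {
                    s for s in nodes
                    if s in child and not nx.descendants(g, s) & bad
                }
            if f.op == "EG":
                return _cycle_reach(g.subgraph(child))
            if f.op == "AF":
                return nodes - _cycle_reach(g.subgraph(nodes - child))
        if isinstance(f, Until):
            left, right = ev(f.left), ev(f.right)
            if f.path == "E":
                return _reach_through(g, left, right)
            not_g = nodes - right
            bad = _reach_through(g, not_g, not_g - left)
            bad |= _cycle_reach(g.subgraph(not_g))
            return nodes - bad
        raise TypeError(f)

    return ev(formula)


# ---------------------------------------------------------------------------
# Betweenness by explicit shortest-path enumeration
# ---------------------------------------------------------------------------

def oracle_betweenness(g: nx.DiGraph) -> dict:
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from((u, v) for u, v in g.edges if u != v)
    score = {v: Fraction(0) for v in h.nodes}
    for s in h.nodes:
        for t in h.nodes:
            if s == t or not nx.has_path(h, s, t):
                continue
            paths = list(nx.all_shortest_paths(h, s, t))
            for v in h.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                if through:
                    score[v] += Fraction(through, len(paths))
    return score


# ---------------------------------------------------------------------------
# Attractors / bifurcation by exhaustive scans
# ---------------------------------------------------------------------------

def oracle_terminal_sccs(g: nx.DiGraph) -> list[frozenset]:
    out = []
    for comp in nx.strongly_connected_components(g):
        escaping = any(w not in comp for v in comp for w in g.successors(v))
        if not escaping:
            out.append(frozenset(comp))
    return sorted(out, key=lambda c: sorted(c)[0])


def oracle_bifurcation(g: nx.DiGraph, atts: list[frozenset]) -> set:
    out = set()
    union = set().union(*atts) if atts else set()
    for s in g.nodes:
        reach = {s} | nx.descendants(g, s)
        n = sum(1 for a in atts if reach & a)
        if n >= 2 and s not in union:
            out.add(s)
    return out
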