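"""Explicit-state CTL model checking over finite state graphs.

Formulas are evaluated on a Kripke structure (a state graph with a total
transition relation) by fixed-point labeling: ``EX`` via pre-images,
``E[. U .]`` as a least fixed point, ``EG`` as a greatest fixed point, and
the universal operators through the standard dualities. State spaces here
are at most a few hundred states, so sets of state indices are used
directly rather than symbolic BDDs.

Grammar (ASCII)::

    formula := implies
    implies := or ('->' implies)?          # right-associative
    or      := and ('|' and)*
    and     := unary ('&' unary)*
    unary   := '!' unary | EX u | AX u | EF u | AF u | EG u | AG u
             | 'E' '[' f 'U' f ']' | 'A' '[' f 'U' f ']'
             | '(' formula ')' | atom | 'true' | 'false'
    atom    := NAME ('='|'<='|'>='|'<'|'>'|'!=') INT

Atom names are resolved case-insensitively against the graph's declared
variables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "CTLFormula",
    "Atom",
    "Bool",
    "Not",
    "And",
    "Or",
    "Implies",
    "Unary",
    "Until",
    "SatisfactionSet",
    "ModelCheckResult",
    "CTLSyntaxError",
    "TotalityError",
    "parse_ctl",
    "parse_property_file",
    "satisfying_states",
    "model_satisfies",
    "LabeledDigraph",
]


class CTLSyntaxError(ValueError):
    """Syntax error with position information."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class TotalityError(ValueError):
    """A temporal operator was evaluated on a non-total transition relation."""


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    var: str
    op: str  # '=', '<=', '>=', '<', '>', '!='
    const: int

    def __str__(self) -> str:
        return f"{self.var}{self.op}{self.const}"


@dataclass(frozen=True)
class Bool:
    value: bool

    def __str__(self) -> str:
        return "true" if self.value else "false"


@dataclass(frozen=True)
class Not:
    child: "CTLFormula"

    def __str__(self) -> str:
        return f"!({self.child})"


@dataclass(frozen=True)
class And:
    left: "CTLFormula"
    right: "CTLFormula"

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class Or:
    left: "CTLFormula"
    right: "CTLFormula"

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


@dataclass(frozen=True)
class Implies:
    left: "CTLFormula"
    right: "CTLFormula"

    def __str__(self) -> str:
        return f"({self.left} -> {self.right})"


@dataclass(frozen=True)
class Unary:
    op: str  # EX AX EF AF EG AG
    child: "CTLFormula"

    def __str__(self) -> str:
        return f"{self.op}({self.child})"


@dataclass(frozen=True)
class Until:
    path: str  # 'E' or 'A'
    left: "CTLFormula"
    right: "CTLFormula"

    def __str__(self) -> str:
        return f"{self.path}[{self.left} U {self.right}]"


CTLFormula = Union[Atom, Bool, Not, And, Or, Implies, Unary, Until]

_UNARY_OPS = ("EX", "AX", "EF", "AF", "EG", "AG")


def atoms_of(formula: CTLFormula) -> list[Atom]:
    """All atoms occurring in a formula (document order, with repeats)."""
    if isinstance(formula, Atom):
        return [formula]
    if isinstance(formula, Bool):
        return []
    if isinstance(formula, Not):
        return atoms_of(formula.child)
    if isinstance(formula, Unary):
        return atoms_of(formula.child)
    if isinstance(formula, (And, Or, Implies, Until)):
        return atoms_of(formula.left) + atoms_of(formula.right)
    raise TypeError(f"not a CTL formula: {formula!r}")


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<lbrack>\[)|(?P<rbrack>\])"
    r"|(?P<arrow>->)|(?P<and>&&?)|(?P<or>\|\|?)|(?P<not>!(?!=))"
    r"|(?P<cmp><=|>=|!=|=|<|>)|(?P<int>\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*))"
)


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None or m.end() == pos and not text[pos:].strip():
                break
            if m is None:
                raise CTLSyntaxError(f"unexpected character {text[pos]!r}", pos)
            if m.lastgroup is None:
                break
            self.tokens.append((m.lastgroup, m.group(m.lastgroup), m.start(m.lastgroup)))
            pos = m.end()
        if text[pos:].strip():
            raise CTLSyntaxError(f"unexpected character {text[pos:].strip()[0]!r}", pos)
        self.i = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise CTLSyntaxError("unexpected end of formula", len(self.text))
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None or tok[0] != kind:
            pos = tok[2] if tok else len(self.text)
            raise CTLSyntaxError(f"expected {what}", pos)
        return self.next()

    # grammar ---------------------------------------------------------------
    def formula(self) -> CTLFormula:
        left = self.disjunction()
        tok = self.peek()
        if tok and tok[0] == "arrow":
            self.next()
            return Implies(left, self.formula())
        return left

    def disjunction(self) -> CTLFormula:
        node = self.conjunction()
        while (tok := self.peek()) and tok[0] == "or":
            self.next()
            node = Or(node, self.conjunction())
        return node

    def conjunction(self) -> CTLFormula:
        node = self.unary()
        while (tok := self.peek()) and tok[0] == "and":
            self.next()
            node = And(node, self.unary())
        return node

    def unary(self) -> CTLFormula:
        tok = self.peek()
        if tok is None:
            raise CTLSyntaxError("unexpected end of formula", len(self.text))
        kind, value, pos = tok
        if kind == "not":
            self.next()
            return Not(self.unary())
        if kind == "lparen":
            self.next()
            node = self.formula()
            self.expect("rparen", "')'")
            return node
        if kind == "name":
            upper = value.upper()
            if upper in _UNARY_OPS:
                self.next()
                return Unary(upper, self.unary())
            if upper in ("E", "A"):
                nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
                if nxt and nxt[0] == "lbrack":
                    self.next()
                    self.next()
                    left = self.formula()
                    u = self.expect("name", "'U'")
                    if u[1].upper() != "U":
                        raise CTLSyntaxError("expected 'U'", u[2])
                    right = self.formula()
                    self.expect("rbrack", "']'")
                    return Until(upper, left, right)
            if value.lower() == "true":
                self.next()
                return Bool(True)
            if value.lower() == "false":
                self.next()
                return Bool(False)
            self.next()
            cmp_tok = self.expect("cmp", "comparator after variable name")
            const = self.expect("int", "integer constant")
            return Atom(value, cmp_tok[1], int(const[1]))
        raise CTLSyntaxError(f"unexpected token {value!r}", pos)


def parse_ctl(text: str) -> CTLFormula:
    """Parse ``text`` into a CTL AST.

    Raises :class:`CTLSyntaxError` with a character position on failure.
    """
    parser = _Parser(text)
    node = parser.formula()
    tok = parser.peek()
    if tok is not None:
        raise CTLSyntaxError(f"trailing input {tok[1]!r}", tok[2])
    return node


def parse_property_file(text: str) -> dict[str, CTLFormula]:
    """Parse a property file: one ``name: formula`` per line, '#' comments."""
    out: dict[str, CTLFormula] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise CTLSyntaxError(f"line {ln}: expected 'name: formula'", 0)
        name, _, body = line.partition(":")
        name = name.strip()
        if not name or name in out:
            raise CTLSyntaxError(f"line {ln}: missing or duplicate property name", 0)
        out[name] = parse_ctl(body)
    return out


# ---------------------------------------------------------------------------
# Checker
# ---------------------------------------------------------------------------

class LabeledDigraph:
    """Minimal Kripke wrapper for arbitrary digraphs (used in tests and
    synthetic observation encoding): a networkx DiGraph plus a valuation
    ``state -> {variable: level}``."""

    def __init__(self, graph, valuation: dict) -> None:
        self.graph = graph
        self.valuation = valuation

    @property
    def nodes(self):
        return sorted(self.graph.nodes)

    def state_value(self, state, var: str) -> int:
        return self.valuation[state][var]


@dataclass(frozen=True)
class SatisfactionSet:
    formula: CTLFormula
    states: frozenset


@dataclass(frozen=True)
class ModelCheckResult:
    holds: bool
    counterexample: Optional[tuple] = None


class _Model:
    """Indexed view of a state graph for set-based fixed-point labeling."""

    def __init__(self, graph) -> None:
        self.source = graph
        self.states = list(graph.nodes)
        self.index = {s: i for i, s in enumerate(self.states)}
        g = graph.graph
        self.succ: list[list[int]] = [
            sorted(self.index[t] for t in g.successors(s)) for s in self.states
        ]
        self.pred: list[list[int]] = [[] for _ in self.states]
        for i, outs in enumerate(self.succ):
            for j in outs:
                self.pred[j].append(i)
        self.total = all(self.succ)
        # case-insensitive atom-name resolution against declared variables
        self._varmap: Optional[dict[str, str]] = None
        brn = getattr(graph, "brn", None)
        if brn is not None:
            self._varmap = {name.upper(): name for name in brn.state_order}
        elif isinstance(graph, LabeledDigraph) and graph.valuation:
            any_state = next(iter(graph.valuation))
            self._varmap = {v.upper(): v for v in graph.valuation[any_state]}

    def resolve(self, var: str) -> str:
        if self._varmap is None:
            return var
        try:
            return self._varmap[var.upper()]
        except KeyError:
            raise CTLSyntaxError(f"unknown variable {var!r} in atom", 0) from None

    def atom_set(self, atom: Atom) -> frozenset[int]:
        var = self.resolve(atom.var)
        ops = {
            "=": lambda a, b: a == b,
            "!=": lambda a, b: a != b,
            "<=": lambda a, b: a <= b,
            ">=": lambda a, b: a >= b,
            "<": lambda a, b: a < b,
            ">": lambda a, b: a > b,
        }
        fn = ops[atom.op]
        return frozenset(
            i for i, s in enumerate(self.states)
            if fn(self.source.state_value(s, var), atom.const)
        )

    # temporal primitives ---------------------------------------------------
    def require_total(self) -> None:
        if not self.total:
            bad = self.states[next(i for i, o in enumerate(self.succ) if not o)]
            raise TotalityError(
                f"transition relation is not total (state {bad} has no successor); "
                "build the graph with stable-state self-loops"
            )

    def ex(self, target: frozenset[int]) -> frozenset[int]:
        self.require_total()
        return frozenset(i for i in range(len(self.states))
                         if any(j in target for j in self.succ[i]))

    def eu(self, hold: frozenset[int], target: frozenset[int]) -> frozenset[int]:
        self.require_total()
        result = set(target)
        frontier = list(target)
        while frontier:
            j = frontier.pop()
            for i in self.pred[j]:
                if i not in result and i in hold:
                    result.add(i)
                    frontier.append(i)
        return frozenset(result)

    def eg(self, hold: frozenset[int]) -> frozenset[int]:
        self.require_total()
        result = set(hold)
        changed = True
        while changed:
            changed = False
            for i in list(result):
                if not any(j in result for j in self.succ[i]):
                    result.discard(i)
                    changed = True
        return frozenset(result)

    def eval(self, formula: CTLFormula) -> frozenset[int]:
        universe = frozenset(range(len(self.states)))
        if isinstance(formula, Bool):
            return universe if formula.value else frozenset()
        if isinstance(formula, Atom):
            return self.atom_set(formula)
        if isinstance(formula, Not):
            return universe - self.eval(formula.child)
        if isinstance(formula, And):
            return self.eval(formula.left) & self.eval(formula.right)
        if isinstance(formula, Or):
            return self.eval(formula.left) | self.eval(formula.right)
        if isinstance(formula, Implies):
            return (universe - self.eval(formula.left)) | self.eval(formula.right)
        if isinstance(formula, Unary):
            child = self.eval(formula.child)
            if formula.op == "EX":
                return self.ex(child)
            if formula.op == "AX":
                return universe - self.ex(universe - child)
            if formula.op == "EF":
                return self.eu(universe, child)
            if formula.op == "AG":
                return universe - self.eu(universe, universe - child)
            if formula.op == "EG":
                return self.eg(child)
            if formula.op == "AF":
                return universe - self.eg(universe - child)
        if isinstance(formula, Until):
            left = self.eval(formula.left)
            right = self.eval(formula.right)
            if formula.path == "E":
                return self.eu(left, right)
            # A[f U g] == !(E[!g U (!f & !g)] | EG !g)
            not_g = universe - right
            bad = self.eu(not_g, not_g - left) | self.eg(not_g)
            return universe - bad
        raise TypeError(f"not a CTL formula: {formula!r}")


def satisfying_states(graph, formula: CTLFormula) -> SatisfactionSet:
    """Exact satisfaction set of ``formula`` on ``graph``.

    ``graph`` is a :class:`~qualnet.dynamics.StateGraph` (atoms refer to
    network variables) or a :class:`LabeledDigraph`.
    """
    model = _Model(graph)
    sat = model.eval(formula)
    return SatisfactionSet(formula, frozenset(model.states[i] for i in sat))


def model_satisfies(
    graph,
    formula: CTLFormula,
    initial_policy: Union[str, Iterable[Sequence[int]]] = "all_states",
) -> ModelCheckResult:
    """Check whether every designated initial state satisfies ``formula``.

    ``initial_policy`` is ``"all_states"`` or an explicit non-empty set of
    states. Returns the first violating initial state (in canonical node
    order) as a counterexample when the check fails.
    """
    model = _Model(graph)
    sat = model.eval(formula)
    if isinstance(initial_policy, str):
        if initial_policy != "all_states":
            raise ValueError(f"unknown initial policy {initial_policy!r}")
        initial = list(range(len(model.states)))
    else:
        initial_states = [tuple(s) if isinstance(s, (list, tuple)) else s
                          for s in initial_policy]
        if not initial_states:
            raise ValueError("initial state set must be non-empty")
        initial = []
        for s in initial_states:
            if s not in model.index:
                raise ValueError(f"initial state {s} is not a node of the graph")
            initial.append(model.index[s])
        initial.sort()
    for i in initial:
        if i not in sat:
            return ModelCheckResult(False, model.states[i])
    return ModelCheckResult(True, None)
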