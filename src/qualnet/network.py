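"""Data model and I/O for biological regulatory networks (BRNs).

A BRN in the multivalued logical (Thomas) formalism is a labeled directed
graph: nodes are gene/protein variables with a finite integer expression
domain ``{0..max_level}``, and edges are signed, thresholded interactions.
A regulator ``u`` of ``v`` is *effective* in a state when its level is at
or above the edge threshold; an activator is a **resource** of ``v`` when
effective, an inhibitor is a resource when *not* effective (the absence of
an inhibitor favors expression).

The dynamics of a BRN are parameterized by a :class:`ParameterTable`
mapping each ``(variable, resource set)`` pair to a *focal level* ``K`` —
the expression level the variable is attracted toward whenever that
resource set is the one currently realized.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "GeneVariable",
    "Interaction",
    "BRN",
    "ParameterTable",
    "ConstraintSet",
    "NetworkValidationError",
    "NetworkParseError",
    "load_network",
    "dump_network",
    "resources",
    "resource_sets",
    "validate_parameter_table",
    "brn_to_sif",
    "sif_to_interactions",
    "parameter_table_to_csv",
    "parameter_table_from_csv",
]


class NetworkParseError(ValueError):
    """Raised when a network document cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a network document parses but violates an invariant."""


@dataclass(frozen=True)
class GeneVariable:
    """A network variable with expression domain ``{0..max_level}``."""

    name: str
    max_level: int = 1

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkValidationError("variable name must be non-empty")
        if self.max_level < 1:
            raise NetworkValidationError(
                f"variable {self.name!r}: max_level must be >= 1, got {self.max_level}"
            )

    @property
    def domain(self) -> range:
        return range(self.max_level + 1)


@dataclass(frozen=True)
class Interaction:
    """A signed, thresholded regulatory edge ``source -> target``.

    ``sign`` is ``'+'`` (activation) or ``'-'`` (inhibition); ``threshold``
    is the source level at and above which the edge is effective.
    """

    source: str
    target: str
    sign: str
    threshold: int = 1

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise NetworkValidationError(
                f"interaction {self.source}->{self.target}: sign must be '+' or '-', "
                f"got {self.sign!r}"
            )
        if self.threshold < 1:
            raise NetworkValidationError(
                f"interaction {self.source}->{self.target}: threshold must be >= 1"
            )


class BRN:
    """A validated biological regulatory network.

    Parameters
    ----------
    variables:
        Ordered sequence of :class:`GeneVariable`; order is the default
        ``state_order``.
    interactions:
        Signed, thresholded edges between declared variables.
    state_order:
        Optional permutation of variable names fixing how state tuples are
        printed and indexed. Defaults to declaration order.
    """

    def __init__(
        self,
        variables: Sequence[GeneVariable],
        interactions: Sequence[Interaction] = (),
        state_order: Optional[Sequence[str]] = None,
    ) -> None:
        self.variables: tuple[GeneVariable, ...] = tuple(variables)
        self.interactions: tuple[Interaction, ...] = tuple(interactions)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate variable names in network")
        self._by_name = {v.name: v for v in self.variables}
        if state_order is None:
            state_order = names
        self.state_order: tuple[str, ...] = tuple(state_order)
        if sorted(self.state_order) != sorted(names):
            raise NetworkValidationError(
                "state_order must be a permutation of the declared variable names"
            )
        self._order_index = {n: i for i, n in enumerate(self.state_order)}
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.interactions:
            for endpoint in (e.source, e.target):
                if endpoint not in self._by_name:
                    raise NetworkValidationError(
                        f"interaction {e.source}->{e.target} references undeclared "
                        f"variable {endpoint!r}"
                    )
            if e.threshold > self._by_name[e.source].max_level:
                raise NetworkValidationError(
                    f"interaction {e.source}->{e.target}: threshold {e.threshold} "
                    f"exceeds max_level {self._by_name[e.source].max_level} of source"
                )
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise NetworkValidationError(
                    f"duplicate interaction {e.source}->{e.target}"
                )
            seen_pairs.add(pair)
        # incoming edges per target, ordered by source declaration order
        decl = {n: i for i, n in enumerate(names)}
        self._regulators: dict[str, tuple[Interaction, ...]] = {n: () for n in names}
        for n in names:
            incoming = [e for e in self.interactions if e.target == n]
            incoming.sort(key=lambda e: decl[e.source])
            self._regulators[n] = tuple(incoming)

    # -- basic accessors ---------------------------------------------------
    def variable(self, name: str) -> GeneVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise NetworkValidationError(f"unknown variable {name!r}") from None

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def regulators(self, target: str) -> tuple[Interaction, ...]:
        """Incoming interactions of ``target`` in declaration order."""
        self.variable(target)
        return self._regulators[target]

    def state_index(self, name: str) -> int:
        self.variable(name)
        return self._order_index[name]

    def level_in_state(self, state: Sequence[int], name: str) -> int:
        return state[self.state_index(name)]

    def n_states(self) -> int:
        n = 1
        for name in self.state_order:
            n *= self._by_name[name].max_level + 1
        return n

    def check_state(self, state: Sequence[int]) -> tuple[int, ...]:
        """Validate a state tuple against the domain; returns it as a tuple."""
        state = tuple(state)
        if len(state) != len(self.variables):
            raise NetworkValidationError(
                f"state has {len(state)} coordinates, expected {len(self.variables)}"
            )
        for name, level in zip(self.state_order, state):
            if level not in self._by_name[name].domain:
                raise NetworkValidationError(
                    f"level {level} outside domain of {name} "
                    f"(0..{self._by_name[name].max_level})"
                )
        return state

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BRN)
            and self.variables == other.variables
            and set(self.interactions) == set(other.interactions)
            and self.state_order == other.state_order
        )

    def __repr__(self) -> str:
        return (
            f"BRN({len(self.variables)} variables, "
            f"{len(self.interactions)} interactions)"
        )


def resources(brn: BRN, state: Sequence[int], var: str) -> frozenset[str]:
    """The resource set of ``var`` in ``state``.

    A regulator ``u`` with edge ``(threshold t, sign s)`` is a resource when
    ``level(u) >= t`` and ``s == '+'``, or ``level(u) < t`` and ``s == '-'``.
    """
    state = brn.check_state(state)
    out = []
    for e in brn.regulators(var):
        lvl = brn.level_in_state(state, e.source)
        if (lvl >= e.threshold) == (e.sign == "+"):
            out.append(e.source)
    return frozenset(out)


def _canonical_subsets(names: Sequence[str]) -> list[frozenset[str]]:
    """All subsets of ``names``, ordered by size then lexicographically."""
    names = sorted(names)
    out: list[frozenset[str]] = []
    for k in range(len(names) + 1):
        for combo in combinations(names, k):
            out.append(frozenset(combo))
    return out


def resource_sets(brn: BRN, var: str) -> list[frozenset[str]]:
    """All ``2^k`` candidate resource sets of ``var`` in canonical order."""
    regs = [e.source for e in brn.regulators(var)]
    return _canonical_subsets(regs)


class ParameterTable:
    """Map from ``(variable, resource set)`` to a focal level ``K``.

    The table is *complete* for a BRN when it has exactly one entry for
    every variable and every subset of that variable's regulators.
    """

    def __init__(self, entries: Mapping[tuple[str, frozenset[str]], int]) -> None:
        self.entries: dict[tuple[str, frozenset[str]], int] = {
            (var, frozenset(res)): int(k) for (var, res), k in entries.items()
        }

    def k(self, var: str, res: Iterable[str]) -> int:
        key = (var, frozenset(res))
        if key not in self.entries:
            raise KeyError(
                f"no parameter K_{var}({sorted(frozenset(res))}) in table"
            )
        return self.entries[key]

    def max_k(self, var: str) -> int:
        ks = [k for (v, _), k in self.entries.items() if v == var]
        if not ks:
            raise KeyError(f"no entries for variable {var!r}")
        return max(ks)

    def items_for(self, var: str) -> list[tuple[frozenset[str], int]]:
        out = [(res, k) for (v, res), k in self.entries.items() if v == var]
        out.sort(key=lambda it: (len(it[0]), tuple(sorted(it[0]))))
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterTable) and self.entries == other.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:
        return f"ParameterTable({len(self.entries)} entries)"


@dataclass
class ConstraintSet:
    """Constraints restricting admissible parameter tables.

    ``snoussi`` enforces monotonicity ``K_v(w) <= K_v(w')`` for ``w ⊆ w'``
    (adding a resource never lowers the focal level); ``observability``
    requires every interaction to change at least one K value; ``pinned``
    fixes individual entries; ``level_caps`` bounds K per variable.
    """

    snoussi: bool = False
    observability: bool = False
    pinned: dict[tuple[str, frozenset[str]], int] = field(default_factory=dict)
    level_caps: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate_against(self, brn: BRN) -> None:
        for (var, res), k in self.pinned.items():
            subsets = resource_sets(brn, var)
            if frozenset(res) not in subsets:
                raise NetworkValidationError(
                    f"pinned entry K_{var}({sorted(res)}) does not name a subset "
                    f"of the regulators of {var}"
                )
            if k not in brn.variable(var).domain:
                raise NetworkValidationError(
                    f"pinned K_{var}({sorted(res)})={k} outside domain of {var}"
                )
        for var in self.level_caps:
            brn.variable(var)


@dataclass(frozen=True)
class TableViolation:
    kind: str  # "missing" | "extra" | "domain" | "snoussi" | "observability"
    variable: str
    detail: str


def validate_parameter_table(
    brn: BRN, table: ParameterTable, constraints: Optional[ConstraintSet] = None
) -> list[TableViolation]:
    """Diagnostic scan of a parameter table against a BRN and constraints.

    Returns an empty list when the table is complete, in-domain and (when
    the corresponding flags are set) satisfies the Snoussi monotonicity and
    observability conditions.
    """
    constraints = constraints or ConstraintSet()
    out: list[TableViolation] = []
    expected: set[tuple[str, frozenset[str]]] = set()
    for v in brn.variables:
        for res in resource_sets(brn, v.name):
            expected.add((v.name, res))
    for key in sorted(expected - set(table.entries), key=_key_sort):
        out.append(TableViolation("missing", key[0], f"K_{key[0]}({sorted(key[1])})"))
    for key in sorted(set(table.entries) - expected, key=_key_sort):
        out.append(TableViolation("extra", key[0], f"K_{key[0]}({sorted(key[1])})"))
    for (var, res), k in sorted(table.entries.items(), key=lambda it: _key_sort(it[0])):
        if (var, res) in expected and k not in brn.variable(var).domain:
            out.append(
                TableViolation("domain", var, f"K_{var}({sorted(res)})={k} out of domain")
            )
    if constraints.snoussi:
        for v in brn.variables:
            subsets = [s for s in resource_sets(brn, v.name)
                       if (v.name, s) in table.entries]
            for a in subsets:
                for b in subsets:
                    if a < b and table.k(v.name, a) > table.k(v.name, b):
                        out.append(
                            TableViolation(
                                "snoussi",
                                v.name,
                                f"K_{v.name}({sorted(a)})={table.k(v.name, a)} > "
                                f"K_{v.name}({sorted(b)})={table.k(v.name, b)}",
                            )
                        )
    if constraints.observability:
        for e in brn.interactions:
            regs = [x.source for x in brn.regulators(e.target)]
            others = [r for r in regs if r != e.source]
            observable = False
            for sub in _canonical_subsets(others):
                with_u = sub | {e.source}
                if (e.target, sub) in table.entries and (e.target, with_u) in table.entries:
                    if table.k(e.target, sub) != table.k(e.target, with_u):
                        observable = True
                        break
            if not observable:
                out.append(
                    TableViolation(
                        "observability",
                        e.target,
                        f"interaction {e.source}->{e.target} changes no K value",
                    )
                )
    return out


def _key_sort(key: tuple[str, frozenset[str]]):
    var, res = key
    return (var, len(res), tuple(sorted(res)))


# ---------------------------------------------------------------------------
# Network document I/O (YAML)
# ---------------------------------------------------------------------------

def load_network(spec_text: str) -> BRN:
    """Parse a network spec document into a validated :class:`BRN`.

    The document is YAML with the shape::

        variables:
          - {name: DNMT1, max: 2}
        interactions:
          - {source: CMYC, target: DNMT1, sign: "+", threshold: 1}
        state_order: [DNMT1, ...]       # optional

    Thresholds default to 1 when omitted.
    """
    try:
        doc = yaml.safe_load(spec_text)
    except yaml.YAMLError as exc:
        raise NetworkParseError(f"invalid network document: {exc}") from exc
    if not isinstance(doc, dict) or "variables" not in doc:
        raise NetworkParseError("network document must declare 'variables'")
    variables = []
    for i, entry in enumerate(doc["variables"]):
        if isinstance(entry, str):
            entry = {"name": entry}
        if not isinstance(entry, dict) or "name" not in entry:
            raise NetworkParseError(f"variables[{i}]: expected a name")
        variables.append(GeneVariable(str(entry["name"]), int(entry.get("max", 1))))
    interactions = []
    for i, entry in enumerate(doc.get("interactions", []) or []):
        if not isinstance(entry, dict):
            raise NetworkParseError(f"interactions[{i}]: expected a mapping")
        missing = {"source", "target", "sign"} - set(entry)
        if missing:
            raise NetworkParseError(
                f"interactions[{i}]: missing fields {sorted(missing)}"
            )
        interactions.append(
            Interaction(
                str(entry["source"]),
                str(entry["target"]),
                str(entry["sign"]),
                int(entry.get("threshold", 1)),
            )
        )
    return BRN(variables, interactions, doc.get("state_order"))


def dump_network(brn: BRN) -> str:
    """Serialize a BRN back to the YAML spec format (round-trips load)."""
    doc = {
        "variables": [{"name": v.name, "max": v.max_level} for v in brn.variables],
        "interactions": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "threshold": e.threshold,
            }
            for e in brn.interactions
        ],
        "state_order": list(brn.state_order),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def brn_to_sif(brn: BRN) -> str:
    """Interaction list as SIF text (source, sign, target) for graph viewers."""
    lines = [f"{e.source}\t{e.sign}\t{e.target}" for e in brn.interactions]
    return "\n".join(lines) + ("\n" if lines else "")


def sif_to_interactions(text: str) -> list[Interaction]:
    out = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise NetworkParseError(f"SIF line {ln}: expected 'source sign target'")
        out.append(Interaction(parts[0], parts[2], parts[1]))
    return out


# ---------------------------------------------------------------------------
# Parameter table I/O (CSV: variable, resource_set, K)
# ---------------------------------------------------------------------------

def parameter_table_to_csv(table: ParameterTable) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["variable", "resource_set", "K"])
    for (var, res), k in sorted(table.entries.items(), key=lambda it: _key_sort(it[0])):
        writer.writerow([var, ";".join(sorted(res)), k])
    return buf.getvalue()


def parameter_table_from_csv(text: str) -> ParameterTable:
    reader = csv.DictReader(io.StringIO(text))
    required = {"variable", "resource_set", "K"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise NetworkParseError(
            "parameter CSV must have columns variable, resource_set, K"
        )
    entries: dict[tuple[str, frozenset[str]], int] = {}
    for i, row in enumerate(reader, 2):
        res = frozenset(x for x in row["resource_set"].split(";") if x)
        key = (row["variable"], res)
        if key in entries:
            raise NetworkParseError(f"line {i}: duplicate entry for {key}")
        entries[key] = int(row["K"])
    return ParameterTable(entries)
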