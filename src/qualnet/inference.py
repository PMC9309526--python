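"""Exhaustive logical-parameter enumeration with CTL filtering.

This is the parameter-identification step of the qualitative-modeling
pipeline: all parameter tables compatible with the declared constraints
are generated (per-variable candidate K-vectors filtered independently,
then combined as a cartesian product), each candidate's asynchronous state
graph is built, and candidates whose graph violates any of the encoded
observations (CTL formulas, checked from every state by default) are
eliminated. The surviving tables are the models consistent with the
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

from .ctl import CTLFormula, model_satisfies
from .dynamics import StateSpace, build_state_graph
from .network import (
    BRN,
    ConstraintSet,
    ParameterTable,
    parameter_table_from_csv,
    resource_sets,
)

__all__ = [
    "ModelCandidate",
    "SurvivorSet",
    "EnumerationGuardError",
    "TableEnumeration",
    "enumerate_tables",
    "ctl_filter",
    "select_models",
    "export_survivor_matrix",
    "survivor_matrix_to_tables",
]


class EnumerationGuardError(RuntimeError):
    """The candidate space exceeds the configured guard; pin or cap K values."""


@dataclass(frozen=True)
class ModelCandidate:
    id: str
    brn: BRN
    table: ParameterTable


@dataclass
class SurvivorSet:
    """Models passing every filter formula, plus enumeration metadata."""

    brn: BRN
    survivors: list[ModelCandidate]
    total_candidates: int
    per_variable_counts: dict[str, int]
    n_checked: int = 0
    constraints: Optional[ConstraintSet] = None
    formula_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.survivors)

    def ids(self) -> list[str]:
        return [m.id for m in self.survivors]


def _per_variable_candidates(
    brn: BRN, var: str, constraints: ConstraintSet
) -> tuple[list[frozenset[str]], list[tuple[int, ...]]]:
    """All admissible K-vectors of ``var`` over its canonical subset order."""
    subsets = resource_sets(brn, var)
    pos = {s: i for i, s in enumerate(subsets)}
    max_level = brn.variable(var).max_level
    lo, hi = constraints.level_caps.get(var, (0, max_level))
    hi = min(hi, max_level)
    pins = {
        pos[frozenset(res)]: k
        for (v, res), k in constraints.pinned.items()
        if v == var
    }
    # subset-inclusion pairs for the snoussi check
    incl_pairs = [
        (i, j)
        for i, a in enumerate(subsets)
        for j, b in enumerate(subsets)
        if a < b
    ]
    # per incoming edge, the (without, with) index pairs for observability
    edges = []
    regs = [e.source for e in brn.regulators(var)]
    for u in regs:
        pairs = [
            (pos[s], pos[s | {u}]) for s in subsets if u not in s
        ]
        edges.append(pairs)

    out: list[tuple[int, ...]] = []
    for vec in product(range(lo, hi + 1), repeat=len(subsets)):
        if any(vec[i] != k for i, k in pins.items()):
            continue
        if constraints.snoussi and any(vec[i] > vec[j] for i, j in incl_pairs):
            continue
        if constraints.observability and any(
            all(vec[i] == vec[j] for i, j in pairs) for pairs in edges
        ):
            continue
        out.append(vec)
    return subsets, out


class TableEnumeration:
    """Lazy cartesian product of per-variable candidate K-vectors.

    ``len()`` gives the total count without materializing tables; iteration
    yields complete :class:`ParameterTable` objects in deterministic order
    (variables in declaration order, K-vectors in lexicographic order).
    """

    def __init__(
        self, brn: BRN, constraints: Optional[ConstraintSet] = None,
        guard: int = 10_000_000,
    ) -> None:
        self.brn = brn
        self.constraints = constraints or ConstraintSet()
        self.constraints.validate_against(brn)
        self.subsets: dict[str, list[frozenset[str]]] = {}
        self.vectors: dict[str, list[tuple[int, ...]]] = {}
        for v in brn.variables:
            subs, vecs = _per_variable_candidates(brn, v.name, self.constraints)
            self.subsets[v.name] = subs
            self.vectors[v.name] = vecs
        self.per_variable_counts = {
            name: len(vecs) for name, vecs in self.vectors.items()
        }
        total = 1
        for n in self.per_variable_counts.values():
            total *= n
        self.total = total
        if total > guard:
            raise EnumerationGuardError(
                f"candidate space has {total} tables "
                f"(per-variable counts {self.per_variable_counts}); "
                "pin entries or cap levels to reduce it"
            )

    def __len__(self) -> int:
        return self.total

    def __iter__(self) -> Iterator[ParameterTable]:
        names = [v.name for v in self.brn.variables]
        for combo in product(*(self.vectors[n] for n in names)):
            entries: dict[tuple[str, frozenset[str]], int] = {}
            for name, vec in zip(names, combo):
                for sub, k in zip(self.subsets[name], vec):
                    entries[(name, sub)] = k
            yield ParameterTable(entries)


def enumerate_tables(
    brn: BRN, constraints: Optional[ConstraintSet] = None, guard: int = 10_000_000
) -> TableEnumeration:
    """Enumerate all constraint-compatible parameter tables of ``brn``."""
    return TableEnumeration(brn, constraints, guard)


def ctl_filter(
    brn: BRN,
    formulas: Union[Mapping[str, CTLFormula], Sequence[CTLFormula]],
    constraints: Optional[ConstraintSet] = None,
    initial_policy: Union[str, Iterable] = "all_states",
    guard: int = 10_000_000,
    max_states: int = 1_000_000,
) -> SurvivorSet:
    """Keep the enumerated tables whose state graph satisfies every formula.

    Each candidate's full-space asynchronous graph is built with
    stable-state self-loops and every formula is checked under
    ``initial_policy`` (default: from all states). Survivor ids are
    assigned in enumeration order (``M1``, ``M2``, ...).
    """
    if isinstance(formulas, Mapping):
        names = tuple(formulas.keys())
        formula_list = list(formulas.values())
    else:
        formula_list = list(formulas)
        names = tuple(str(f) for f in formula_list)
    if not formula_list:
        raise ValueError("at least one filter formula is required")
    enum = enumerate_tables(brn, constraints, guard)
    space = StateSpace(brn, max_states=max_states)
    survivors: list[ModelCandidate] = []
    n_checked = 0
    for table in enum:
        n_checked += 1
        graph = build_state_graph(brn, table, add_stable_selfloops=True, space=space)
        if all(
            model_satisfies(graph, f, initial_policy).holds for f in formula_list
        ):
            survivors.append(ModelCandidate(f"M{len(survivors) + 1}", brn, table))
    return SurvivorSet(
        brn=brn,
        survivors=survivors,
        total_candidates=len(enum),
        per_variable_counts=enum.per_variable_counts,
        n_checked=n_checked,
        constraints=enum.constraints,
        formula_names=names,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

Criterion = Union[
    tuple[str, str, int],                 # ("max_k", variable, value)
    tuple[str, Sequence[int]],            # ("index", [0-based indices])
    Callable[[ParameterTable], bool],     # predicate on the table
]


def select_models(survivors: SurvivorSet, criterion: Criterion) -> SurvivorSet:
    """Subset of survivors matching a selection criterion.

    Supported criteria: ``("max_k", var, value)`` keeps models whose
    maximum K for ``var`` equals ``value``; ``("index", [i, ...])`` selects
    by position; any callable is used as a predicate on the table. An empty
    selection is returned as-is (callers may warn), never raised.
    """
    if not survivors.survivors:
        raise ValueError("cannot select from an empty survivor set")
    if callable(criterion):
        keep = [m for m in survivors.survivors if criterion(m.table)]
    elif criterion and criterion[0] == "max_k":
        _, var, value = criterion
        keep = [m for m in survivors.survivors if m.table.max_k(var) == value]
    elif criterion and criterion[0] == "index":
        idx = set(criterion[1])
        keep = [m for i, m in enumerate(survivors.survivors) if i in idx]
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    return SurvivorSet(
        brn=survivors.brn,
        survivors=keep,
        total_candidates=survivors.total_candidates,
        per_variable_counts=survivors.per_variable_counts,
        n_checked=survivors.n_checked,
        constraints=survivors.constraints,
        formula_names=survivors.formula_names,
    )


# ---------------------------------------------------------------------------
# Survivor matrix export (heat-map shaped: rows = parameters, cols = models)
# ---------------------------------------------------------------------------

def export_survivor_matrix(survivors: SurvivorSet) -> pd.DataFrame:
    """Survivor tables as a matrix: one row per ``(variable, resource set)``
    key, one column per model id, cells = K. Suitable for heat-map plots."""
    if not survivors.survivors:
        raise ValueError("cannot export an empty survivor set")
    rows = []
    brn = survivors.brn
    for v in brn.variables:
        for res in resource_sets(brn, v.name):
            rows.append((v.name, ";".join(sorted(res))))
    index = pd.MultiIndex.from_tuples(rows, names=["variable", "resource_set"])
    data = {}
    for m in survivors.survivors:
        data[m.id] = [
            m.table.k(var, frozenset(x for x in res.split(";") if x))
            for var, res in rows
        ]
    return pd.DataFrame(data, index=index)


def survivor_matrix_to_tables(matrix: pd.DataFrame) -> dict[str, ParameterTable]:
    """Inverse of :func:`export_survivor_matrix`."""
    out: dict[str, ParameterTable] = {}
    for model_id in matrix.columns:
        entries = {}
        for (var, res), k in matrix[model_id].items():
            entries[(var, frozenset(x for x in res.split(";") if x))] = int(k)
        out[model_id] = ParameterTable(entries)
    return out
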