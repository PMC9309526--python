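"""Packaged DNMT1-RUNX3 case study: network, observations, and the
end-to-end reproduction driver.

The network couples the maintenance methyltransferase DNMT1 with the tumor
suppressor RUNX3 and its regulators: c-myc activates DNMT1, p21 and p53
inhibit it; DNMT1 (via promoter methylation maintenance) keeps RUNX3
expressed at the qualitative level, while RUNX3 transactivates p21 and
represses c-myc; p53 represses c-myc, activates MDM2, and is inhibited by
MDM2 (the classical p53-MDM2 negative loop). DNMT1 is three-valued (0
normal, 1 elevated, 2 lethal overexpression); all other variables are
Boolean.

The driver reproduces the qualitative findings: 14 parameter tables
survive constraint pruning plus CTL filtering; a working model selected by
the reported qualitative trends exhibits the printed recovery cycle, a
bifurcation state from which pathological and homeostatic regimes are both
still reachable, and a homeostasis state of maximal betweenness centrality
on the displayed slice of the state graph.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Optional

from .analysis import (
    AttractorReport,
    attractors,
    betweenness,
    bifurcation_states,
    centrality_to_csv,
    find_path,
    path_through,
    verify_trajectory,
)
from .ctl import CTLFormula, parse_property_file
from .dynamics import StateGraph, build_state_graph, induced_slice, stable_states
from .inference import (
    SurvivorSet,
    ctl_filter,
    export_survivor_matrix,
    select_models,
)
from .network import BRN, ConstraintSet, ParameterTable, load_network, resource_sets

__all__ = [
    "dnmt1_network",
    "dnmt1_properties",
    "trend_pins",
    "trend_selection",
    "CaseStudyConfig",
    "infer_survivors",
    "working_model",
    "CaseStudyReport",
    "run_dnmt1_analysis",
    "RECOVERY_SEQUENCE",
    "BIFURCATION_STATE",
    "PATHOLOGICAL_MARKER",
    "HOMEOSTASIS_MARKER",
    "HOMEOSTASIS_STATE",
]

# printed landmark states, in the order (DNMT1, RUNX3, P21, CMYC, P53, MDM2)
PATHOLOGICAL_MARKER = (1, 0, 0, 1, 0, 0)
HOMEOSTASIS_MARKER = (0, 1, 1, 0, 1, 0)   # normal profile with active p53
HOMEOSTASIS_STATE = (0, 0, 1, 0, 0, 0)    # most central state of the system
BIFURCATION_STATE = (0, 1, 0, 1, 1, 0)

#: The recovery cycle: oncogene onset, DNMT1 induction, RUNX3-led recovery.
RECOVERY_SEQUENCE = [
    (0, 0, 0, 1, 0, 0),
    (1, 0, 0, 1, 0, 0),
    (1, 1, 0, 1, 0, 0),
    (1, 1, 0, 0, 0, 0),
    (0, 1, 0, 0, 0, 0),
    (0, 1, 1, 0, 0, 0),
    (0, 0, 1, 0, 0, 0),
]

#: Waypoints of the two branches leaving the bifurcation state.
PATHOLOGICAL_WAYPOINTS = [(0, 0, 0, 1, 1, 0), (1, 0, 1, 1, 1, 0)]
HOMEOSTASIS_WAYPOINTS = [(1, 1, 0, 0, 1, 0), (0, 0, 0, 0, 0, 0)]


def dnmt1_network(variant: str = "direct") -> BRN:
    """The packaged DNMT1-RUNX3 network (6 variables, 9 interactions).

    ``variant="direct"`` (default) wires p53 as a direct DNMT1 inhibitor,
    giving DNMT1 three regulators and eight candidate resource sets;
    ``variant="indirect_p53"`` routes the p53 influence through p21 instead.
    """
    fname = {
        "direct": "dnmt1_runx3.yaml",
        "indirect_p53": "dnmt1_runx3_indirect_p53.yaml",
    }[variant]
    text = importlib_resources.files("qualnet.data").joinpath(fname).read_text()
    return load_network(text)


def dnmt1_properties() -> dict[str, CTLFormula]:
    """The two temporal-logic observations filtering the parameter space.

    ``pathogenesis`` asks for a reachable state with lethal DNMT1, c-myc
    on and all tumor suppressors off; ``homeostasis`` asks for a reachable
    regime in which a normal profile always remains reachable. Both are
    checked from every state and are overridable via
    :class:`CaseStudyConfig`.
    """
    text = (
        importlib_resources.files("qualnet.data")
        .joinpath("dnmt1_observations.ctl")
        .read_text()
    )
    return parse_property_file(text)


def trend_pins(brn: BRN) -> dict[tuple[str, frozenset[str]], int]:
    """Parameter pins encoding the reported qualitative regulatory trends.

    These fix every Boolean sub-table to its biologically stated logic and
    leave only DNMT1's response to its resource combinations free:

    - RUNX3 is expressed iff the DNMT1 signal is present;
    - p21 is expressed iff RUNX3 transactivates it;
    - p53 rises iff the MDM2 inhibition signal is absent;
    - MDM2 is induced iff p53 is present;
    - c-myc turns on only when both of its inhibitors (RUNX3, p53) are
      absent — either suppressor alone silences it;
    - DNMT1 is never induced without its activator c-myc (its focal level
      is 0 for every resource set lacking c-myc).
    """
    pins: dict[tuple[str, frozenset[str]], int] = {}
    for var, reg in [
        ("RUNX3", "DNMT1"),
        ("P21", "RUNX3"),
        ("P53", "MDM2"),
        ("MDM2", "P53"),
    ]:
        pins[(var, frozenset())] = 0
        pins[(var, frozenset({reg}))] = 1
    for sub in resource_sets(brn, "CMYC"):
        pins[("CMYC", sub)] = 1 if sub == frozenset({"RUNX3", "P53"}) else 0
    for sub in resource_sets(brn, "DNMT1"):
        if "CMYC" not in sub:
            pins[("DNMT1", sub)] = 0
    return pins


def trend_selection(table: ParameterTable) -> bool:
    """Predicate pinning the working model among the survivors.

    c-myc alone sustains an *elevated* (not lethal) DNMT1 level, the
    presence of either inhibitor p21 or p53 caps DNMT1 below its maximum,
    and only the full resource set (c-myc on, both inhibitors absent)
    drives DNMT1 to the lethal level 2.
    """
    c, p21, p53 = "CMYC", "P21", "P53"
    return (
        table.k("DNMT1", {c}) == 1
        and table.k("DNMT1", {c, p21}) == 1
        and table.k("DNMT1", {c, p53}) == 1
        and table.k("DNMT1", {c, p21, p53}) == 2
    )


@dataclass
class CaseStudyConfig:
    """Configuration of the reproduction driver (all defaults overridable)."""

    snoussi: bool = True
    observability: bool = False
    use_trend_pins: bool = True
    extra_pins: dict = field(default_factory=dict)
    properties: Optional[dict[str, CTLFormula]] = None
    initial_policy: str = "all_states"
    #: display convention of the reported state graph: the slice of levels
    #: the printed trajectories actually visit (DNMT1 below lethal, MDM2 off)
    display_slice: dict = field(
        default_factory=lambda: {"DNMT1": (0, 1), "MDM2": (0, 0)}
    )
    restriction_seed: tuple = BIFURCATION_STATE
    output_dir: Optional[str] = None


@dataclass
class CaseStudyReport:
    """Summary of one end-to-end case-study run."""

    survivor_count: int
    total_candidates: int
    per_variable_counts: dict
    selected_model_id: Optional[str]
    full_nodes: int
    full_edges: int
    display_nodes: int
    display_edges: int
    reachable_nodes: int
    stable_states: list
    attractor_sizes: list
    recovery_ok: bool
    recovery_closes: bool
    bifurcation_is_classified: bool
    bifurcation_set_size: int
    branch_reachability: dict
    waypoints_on_paths: dict
    top_central_full: list
    top_central_display: list
    max_central_display: Optional[tuple]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), indent=2, default=default)


def infer_survivors(config: Optional[CaseStudyConfig] = None) -> SurvivorSet:
    """Enumerate and CTL-filter the case-study parameter space."""
    config = config or CaseStudyConfig()
    brn = dnmt1_network()
    pins = dict(trend_pins(brn)) if config.use_trend_pins else {}
    pins.update(config.extra_pins)
    constraints = ConstraintSet(
        snoussi=config.snoussi,
        observability=config.observability,
        pinned=pins,
    )
    formulas = config.properties or dnmt1_properties()
    return ctl_filter(brn, formulas, constraints, config.initial_policy)


def working_model(
    config: Optional[CaseStudyConfig] = None,
    survivors: Optional[SurvivorSet] = None,
) -> tuple[str, BRN, ParameterTable]:
    """The survivor selected by lethal-level capability plus the reported
    qualitative trends; raises when the selection is empty."""
    survivors = survivors if survivors is not None else infer_survivors(config)
    if survivors.survivors:
        lethal = select_models(survivors, ("max_k", "DNMT1", 2))
        working = select_models(lethal, trend_selection) if lethal.survivors else lethal
        if working.survivors:
            chosen = working.survivors[0]
            return chosen.id, survivors.brn, chosen.table
    raise RuntimeError(
        "no surviving model matches the selection criteria; relax the "
        "constraint flags or property overrides in CaseStudyConfig"
    )


def run_dnmt1_analysis(config: Optional[CaseStudyConfig] = None) -> CaseStudyReport:
    """Run the full case-study pipeline: enumerate -> filter -> select ->
    build graphs -> centrality/attractors/bifurcation -> verify printed
    trajectories; optionally write all artifacts to ``config.output_dir``."""
    config = config or CaseStudyConfig()
    survivors = infer_survivors(config)
    selected_id, brn, selected = working_model(config, survivors)

    full = build_state_graph(brn, selected, add_stable_selfloops=True)
    display = induced_slice(full, config.display_slice)
    reachable = build_state_graph(
        brn, selected, restrict_reachable_from=[config.restriction_seed]
    )

    report_attr = attractors(full)
    markers = AttractorReport.from_markers(
        full,
        {"pathological": PATHOLOGICAL_MARKER, "homeostasis": HOMEOSTASIS_MARKER},
    )
    bif_set = bifurcation_states(full, markers)

    recovery = verify_trajectory(full, RECOVERY_SEQUENCE)
    closure = find_path(full, RECOVERY_SEQUENCE[-1], RECOVERY_SEQUENCE[0])

    branch_reach = {
        "pathological": find_path(full, BIFURCATION_STATE, PATHOLOGICAL_MARKER)
        is not None,
        "homeostasis": find_path(full, BIFURCATION_STATE, HOMEOSTASIS_MARKER)
        is not None,
        "homeostasis_central": find_path(full, BIFURCATION_STATE, HOMEOSTASIS_STATE)
        is not None,
    }
    waypoints = {}
    for name, marker, points in [
        ("pathological", PATHOLOGICAL_MARKER, PATHOLOGICAL_WAYPOINTS),
        ("homeostasis", HOMEOSTASIS_MARKER, HOMEOSTASIS_WAYPOINTS),
    ]:
        waypoints[name] = {
            str(p): path_through(full, BIFURCATION_STATE, p, marker) is not None
            for p in points
        }

    bw_full = betweenness(full)
    bw_disp = betweenness(display)
    top_full = sorted(bw_full.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    top_disp = sorted(bw_disp.items(), key=lambda kv: (-kv[1], kv[0]))[:5]

    report = CaseStudyReport(
        survivor_count=len(survivors),
        total_candidates=survivors.total_candidates,
        per_variable_counts=survivors.per_variable_counts,
        selected_model_id=selected_id,
        full_nodes=full.n_nodes(),
        full_edges=full.n_edges(count_selfloops=False),
        display_nodes=display.n_nodes(),
        display_edges=display.n_edges(count_selfloops=False),
        reachable_nodes=reachable.n_nodes(),
        stable_states=stable_states(full),
        attractor_sizes=sorted(len(a) for a in report_attr.attractors),
        recovery_ok=recovery.ok,
        recovery_closes=closure is not None,
        bifurcation_is_classified=BIFURCATION_STATE in bif_set,
        bifurcation_set_size=len(bif_set),
        branch_reachability=branch_reach,
        waypoints_on_paths=waypoints,
        top_central_full=[(s, float(v)) for s, v in top_full],
        top_central_display=[(s, float(v)) for s, v in top_disp],
        max_central_display=top_disp[0][0] if top_disp else None,
    )

    if config.output_dir:
        _write_artifacts(config.output_dir, survivors, selected, full, display,
                         bw_disp, report)
    return report


def _write_artifacts(outdir, survivors, selected, full, display, bw_disp, report):
    os.makedirs(outdir, exist_ok=True)
    matrix = export_survivor_matrix(survivors)
    matrix.to_csv(os.path.join(outdir, "survivors.csv"))
    full.to_graphml(os.path.join(outdir, "stategraph.graphml"))
    with open(os.path.join(outdir, "stategraph_edges.csv"), "w") as fh:
        fh.write(full.to_edge_csv())
    with open(os.path.join(outdir, "centrality.csv"), "w") as fh:
        fh.write(centrality_to_csv(bw_disp))
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    from .network import parameter_table_to_csv

    with open(os.path.join(outdir, "selected_model.csv"), "w") as fh:
        fh.write(parameter_table_to_csv(selected))
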