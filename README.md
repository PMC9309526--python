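# qualnet

Qualitative modeling of gene regulatory networks in the multivalued logical
(René Thomas) formalism: logical-parameter inference by explicit-state CTL
model checking, asynchronous state-transition graphs, and trajectory /
centrality analysis. The package ships a fully worked case study of the
DNMT1–RUNX3 breast-cancer network, plus a small toolbox for evaluating
binary activity classifiers on compound-screen data (IC50 binarization,
diversity splitting, confusion statistics).

## Who this is for

Systems biologists who want to reason about the *qualitative* dynamics of a
small regulatory network — which regimes are reachable, which states act as
checkpoints, which parameter assignments are consistent with wet-lab
observations — without committing to rate constants. Everything runs on a
laptop; there are no downloads and no external model checkers.

## The model

A **biological regulatory network (BRN)** is a labeled directed graph: each
variable `v` has a finite expression domain `{0..max_v}`, and each edge
`u → v` carries a threshold `τ` and a sign. In a state `s` (one level per
variable), the **resource set** `ω_v(s)` collects the regulators currently
favoring `v`: activators at or above threshold and inhibitors *below*
threshold (the absence of an inhibitor is a resource). A **logical
parameter table** assigns to every pair `(v, ω)` a focal level
`K_v(ω) ∈ {0..max_v}`; in state `s`, variable `v` is attracted toward
`K_v(ω_v(s))` and may move **one unit** toward it. Each eligible variable
yields its own transition (asynchronous, non-deterministic updating), which
gives a finite state-transition graph; a state where every variable sits at
its focal level is stable.

The `K` values are unknowns. They are inferred by **model checking**:
biological observations are written as CTL formulas (`EX/EF/EG/AG/AF/EU/AU`
over atoms like `DNMT1=2`), all parameter tables compatible with the
declared constraints are enumerated — the **Snoussi** constraint makes
`K_v` monotone in `ω`, **observability** requires every edge to matter, and
individual entries can be pinned — and every candidate's state graph is
checked from all states. The survivors are the models consistent with the
observations. Their graphs are then analyzed: terminal strongly connected
components (attractors), shortest trajectories, and raw directed
**betweenness centrality** (exact rational arithmetic), which ranks states
by how many shortest inter-state trajectories pass through them.

## Worked example: the DNMT1–RUNX3 case study

The packaged network has six variables — DNMT1 (domain 0–2: normal,
elevated, lethal), RUNX3, p21, c-myc, p53, MDM2 (Boolean) — and nine
interactions: c-myc activates DNMT1 while p21 and p53 inhibit it; DNMT1
maintains RUNX3 expression; RUNX3 transactivates p21 and represses c-myc;
p53 represses c-myc, activates MDM2, and is inhibited by MDM2. State
tuples print in the order (DNMT1, RUNX3, p21, c-myc, p53, MDM2).

```
$ qualnet casestudy
```

prints (abridged):

```
survivor_count        = 14      of 20 candidate parameter tables
selected_model_id     = M10
full_nodes/full_edges = 96 / 304
display_nodes/edges   = 32 / 80
stable_states         = []
attractor_sizes       = [80]
recovery_ok           = True    recovery_closes = True
bifurcation_is_classified = True
max_central_display   = (0, 0, 1, 0, 0, 0)
```

Reading those numbers:

- **14 of 20 survive.** With the Snoussi constraint plus pins encoding the
  stated regulatory logic (each Boolean sub-table fixed; DNMT1 never
  induced without c-myc), only DNMT1's response to its four
  c-myc-containing resource sets is free — 20 monotone candidates. The two
  temporal observations (a reachable lethal-DNMT1 / suppressed-TSG state,
  and a recurrent normal regime) eliminate exactly the six tables that
  never reach DNMT1 level 2.
- **The working model** is the survivor matching the reported trends:
  c-myc alone sustains elevated DNMT1 (`K=1`), either inhibitor caps it
  below maximum, and only the full resource set drives it to the lethal
  level (`K=2`).
- **96 states, no stable state, one 80-state terminal component.** The
  p53–MDM2 negative loop keeps the system oscillating; pathological and
  homeostatic behaviors are cycles inside one recurrent set, i.e. recovery
  remains possible from the pathological state.
- **The recovery cycle verifies**: every printed step of
  `(0,0,0,1,0,0) → (1,0,0,1,0,0) → (1,1,0,1,0,0) → (1,1,0,0,0,0) →
  (0,1,0,0,0,0) → (0,1,1,0,0,0) → (0,0,1,0,0,0)` is an edge, and the loop
  closes back through c-myc onset at `(0,0,1,1,0,0)`.
- **The bifurcation state `(0,1,0,1,1,0)`** can still evolve to both the
  pathological marker `(1,0,0,1,0,0)` and the homeostatic marker
  `(0,1,1,0,1,0)`; the printed waypoints of both branches lie on such
  paths.
- **`(0,0,1,0,0,0)` is the most central state** (betweenness 109.49) on
  the 32-state displayed slice of the dynamics (DNMT1 below lethal, MDM2
  off) — the homeostasis checkpoint the system funnels through.

`qualnet casestudy --out DIR` additionally writes the survivor heat-map
matrix, the GraphML/CSV state graph, the centrality table, and the full
JSON report. The same pipeline is available programmatically via
`qualnet.casestudy.run_dnmt1_analysis()`, and every stage (network I/O,
enumeration, CTL checking, graph analysis) is an ordinary library call —
see the module docstrings.

## Compound-screen evaluation

`qualnet.mleval` implements the data-preparation and scoring conventions
of a small-molecule inhibitor screen: fragment/duplicate/inconsistency
filtering, dual-cut-off IC50 binarization (≤ 10 µM active, > 18 µM
least-active, the window excluded), maximin diversity splitting on
standardized descriptors, and the seven confusion statistics (accuracy,
sensitivity, specificity, precision, recall, F-measure, MCC — reported as
undefined rather than zero when a marginal vanishes). The classifier is a
pluggable sklearn-style estimator; `qualnet.synthetic` generates seeded
compound tables for testing.

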