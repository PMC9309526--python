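# Methods

## Model and semantics

The package implements the multivalued logical formalism for regulatory
networks. A network is a labeled digraph of variables with finite integer
domains; an edge `u → v` carries a threshold `τ ≥ 1` and a sign. Variable
domains are declared explicitly in the network document rather than derived
from outgoing thresholds: the case-study variable DNMT1 must reach level 2
although its only functional outgoing threshold is 1, and declaration is
the only encoding consistent with both.

In a state `s`, the resource set `ω_v(s)` of `v` contains each regulator
`u` with `s_u ≥ τ` for activators and `s_u < τ` for inhibitors — absent
inhibitors count as resources. Resource sets are sets of regulator *names*;
the canonical enumeration order of the `2^k` subsets is by size, then
lexicographic, so exports and cartesian products are deterministic.

Dynamics are **asynchronous and unitary**: in state `s`, every variable
whose level differs from its focal level `K_v(ω_v(s))` contributes one
transition moving it a single unit toward the focal level. Unitary stepping
(rather than jumping to the focal level) is the standard convention and is
required for the case study's printed one-step trajectories to be edges.
Stable states receive self-loops by default so the transition relation is
total — the Kripke-structure requirement of CTL semantics; the checker
raises an explicit totality error otherwise rather than silently repairing
the graph.

## CTL checking

The checker is explicit-state: satisfaction sets are computed by
fixed-point labeling (`EX` by pre-image, `E[· U ·]` as a least fixed point,
`EG` as a greatest fixed point, universal operators by duality) over state
sets indexed by position. State spaces in scope are at most a few hundred
states, so symbolic BDDs would buy nothing and cost auditability. The
grammar is plain ASCII (`EX AX EF AF EG AG`, `E[· U ·]`, `! & | ->`,
atoms `VAR op INT`); atom names resolve case-insensitively against the
declared variables. The test suite checks the implementation extensionally
against an independent closure-based semantics (reachability via graph
descendants, `EG` via cycle-reachability in the induced subgraph) on
thousands of random Kripke structures.

## Parameter inference

Candidate parameter tables are enumerated per variable first — each
variable's K-vector stream is filtered independently by the Snoussi
monotonicity constraint (`K_v(ω) ≤ K_v(ω′)` for `ω ⊆ ω′`), the
observability constraint (every edge changes some K value), pins, and level
caps — and then combined as a cartesian product. This ordering is what
makes desk-scale runs possible: the case-study space is ~2.7×10⁷ tables
unconstrained but 20 under the shipped configuration. A configurable guard
aborts oversized enumerations and reports the per-variable counts so the
user knows what to pin. Each surviving candidate is the one whose
full-space state graph (with self-loops) satisfies every observation
formula from every state; checking from all states is the default initial
policy, overridable per run. Survivor ids `M1, M2, …` follow deterministic
enumeration order.

## Case-study configuration and its rationale

Four conventions of the original analysis tooling are not recoverable from
the published account, so the case study ships them as explicit,
overridable configuration with the following defaults:

- **Wiring.** p53 is encoded as a *direct* DNMT1 inhibitor, which is what
  gives DNMT1 three regulators and eight resource sets; the alternative
  indirect wiring (p53 acting through p21) is packaged as a variant
  network document. All thresholds are 1.
- **Constraints.** Snoussi is on; observability is off; pins encode the
  qualitative regulatory logic stated for the selected models: RUNX3 on
  iff DNMT1 present; p21 on iff RUNX3 present; p53 on iff MDM2 absent;
  MDM2 on iff p53 present; c-myc on only when *both* inhibitors (RUNX3,
  p53) are absent; DNMT1 never induced without c-myc. This leaves DNMT1's
  four c-myc-containing resource sets free: 20 Snoussi-monotone
  candidates. The two observation formulas eliminate exactly the six that
  never reach DNMT1 level 2, leaving 14 survivors. The count is
  insensitive to the precise reconstruction of the observation formulas
  (five variants were tried; all give 14 under this configuration), which
  is why this configuration is the shipped default.
- **Observations.** `pathogenesis: EF(DNMT1=2 & CMYC=1 & RUNX3=0 & P21=0
  & P53=0)` and `homeostasis: EF(AG(EF(DNMT1<=1 & RUNX3=1 & P21=1 &
  CMYC=0)))`, both checked from all states and overridable via the
  property file or `CaseStudyConfig`.
- **Selection.** Among survivors, the working model is selected by
  `max K_DNMT1 = 2` plus the stated trends (c-myc alone sustains level 1;
  either inhibitor caps DNMT1 at 1; the full resource set reaches 2).
  This pins a unique table.

Two findings of the analysis deserve explicit statement. First, the
selected model has **no stable state and a single 80-state terminal SCC**:
the p53–MDM2 loop oscillates everywhere, and the pathological and
homeostatic cycles are mutually reachable (the recovery trajectory *is*
the path from the pathological state back to homeostasis). Classifying a
bifurcation state by "reaches ≥ 2 terminal SCCs" is therefore vacuous
here; the package instead supports *marker-designated* regimes in
`AttractorReport.from_markers`, and the case study designates the
pathological state `(1,0,0,1,0,0)` and the homeostatic state
`(0,1,1,0,1,0)`. Bifurcation analysis with genuine terminal SCCs remains
the default and is what the random-graph property tests exercise. Second,
the printed recovery "cycle" closes through the intermediate
`(0,0,1,1,0,0)` (c-myc onset, then p21 decay) — the direct closing edge
would change two coordinates at once, which unitary asynchronous semantics
forbids.

## Displayed-graph convention and centrality

The reported state graph of the case study is the induced slice on the
levels the trajectories actually visit — DNMT1 ∈ {0,1} and MDM2 = 0 —
which has exactly 32 of the 96 states (80 non-loop edges). Betweenness is
raw (unnormalized), directed, self-loops excluded, computed by Brandes'
dependency accumulation with `fractions.Fraction` arithmetic so tie-heavy
small graphs suffer no float drift. On the displayed slice the homeostasis
state `(0,0,1,0,0,0)` attains the maximum betweenness; on the full
96-state graph (also reported) the pathological hub `(1,0,0,1,0,0)` ranks
first instead — the slice, not the full space, is the graph on which the
centrality claim holds, and both rankings appear in the report.

## Synthetic data

Generators are pure functions of `(seed, parameters)`. Random networks
draw each ordered variable pair (self-regulation allowed) with the given
density, signs uniformly, and thresholds uniformly in the source's range.
Random tables sample K values uniformly; with the Snoussi flag they are
closed upward over the subset lattice, so monotonicity holds by
construction. Observation sets encode sampled transitions as
`state-characterization -> EX successor-characterization` facts, staying
inside the implemented CTL fragment; by construction every fact holds on
the source graph, which underwrites the parameter-recovery suite (the
generating table always survives filtering by its own full transition
list).

The compound-table generator emulates the *shape* of a curated inhibitor
screen, not its chemistry: IC50 values come from a two-component normal
mixture on the log10 scale (actives centered near 1 µM, least-actives
near 150 µM, ~68% active) clipped to 0.01–1,600 µM, so the distribution
is bimodal around the 10 µM threshold with some compounds in the excluded
(10, 18] window; the ten descriptor columns are Gaussian with a
configurable class-mean separation (full shift on the first descriptor,
attenuated on the rest). Passing tests on these tables demonstrates the
correctness of the filtering, splitting, and scoring machinery — not
classifier performance on real descriptor sets, which depend on
proprietary descriptor software and curated assay data and are out of
scope.

## Evaluation statistics

The seven statistics are computed exactly from integer confusion counts
with class 1 positive. MCC is reported as *undefined* (`None`) when any
marginal vanishes — the denominator is zero and coercing to 0 would
overstate what the data show; F-measure follows the standard zero
convention when precision and recall are both defined but zero, and is
undefined only when precision itself is (no positive predictions). The
dual IC50 cut-off (active ≤ 10 µM, least-active > 18 µM, gap excluded) is
the implemented rule; both bounds are arguments. The duplicate-consistency
ratio (default 10×) is a documented package default, not a literature
value; repeat measurements within the ratio collapse to their geometric
mean. The diversity split is greedy maximin on z-scored descriptors,
seeded only for exact ties, so it is reproducible and deterministic.

## Numerical and degenerate-input choices

- Exact arithmetic wherever ties matter: Fractions in betweenness, integer
  set operations in the checker; no tolerances are needed anywhere in the
  qualitative pipeline.
- Empty-path convention: `find_path(s, s)` is `[s]`; a one-state
  trajectory verifies vacuously; unknown states in a trajectory are
  reported per position rather than raising.
- Empty survivor selections return empty (callers may warn); selecting
  from an empty survivor *set* raises, as does an empty initial-state set
  for the checker.
- Guards: state spaces cap at 10⁶ states, enumerations at 10⁷ tables by
  default; both configurable and both reported with actionable counts.

## Problem sizes used in the shipped test suite

The property suites run at sizes where exhaustive oracles stay exact:
CTL on 1,000 random Kripke structures of ≤ 12 states against the
closure-based oracle; betweenness on 1,000 random digraphs of ≤ 10 nodes
against explicit path enumeration; attractors on 1,000 totalized digraphs
against a no-escaping-edge scan; parameter recovery on 50 random Boolean
networks (2–4 variables, Snoussi-constrained candidate spaces of ≤ 600
tables); metrics on 1,000 random confusion matrices. The case-study runs
use the full 96-state space throughout.

## Known limitations

- Asynchronous unitary semantics only; no synchronous, probabilistic, or
  delay-aware updating, no piecewise-linear hybrid refinement.
- CTL only (no LTL/CTL*, no fairness); counterexamples are single
  violating states, not traces.
- Enumeration is explicit; problems beyond a few thousand candidate
  tables require pinning or caps rather than SAT/BDD technology.
- The displayed-slice convention (DNMT1 ≤ 1, MDM2 = 0) reproduces the
  reported 32-state graph and its centrality ranking, but the original
  figure's exact edge count (79) differs from the slice's by one and is
  not reconstructible from the published account.
- Topology is an input: the package infers parameters given a network; it
  does not learn network structure from expression data.
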