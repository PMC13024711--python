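# Methods

## Task model

The Balance Beam task is modeled as a finite state automaton.  Each of the
four weights (50, 100, 300, 500 g) occupies exactly one of ten slots: held
by student A, held by student B, or hung at one of four lever positions on
either side (A1–A4, B1–B4).  Slot assignments are independent — several
weights may share a peg — so the state space is 10⁴ = 10,000.  States are
encoded by a mixed-radix base-10 code over the weight order (50, 100, 300,
500) with slot digit order (HELD_A, HELD_B, A1..A4, B1..B4); the code is a
bijection onto [0, 9999] and code 0 is the initial state (A holds all four
weights).

Moves change one weight's slot:

| kind   | from → to                  | actor restriction                  |
|--------|----------------------------|------------------------------------|
| PASS   | hand → partner's hand      | the holder                         |
| HANG   | hand → own-side position   | the holder, own side only          |
| REMOVE | own-side position → hand   | the side owner, into their own hand|
| SHIFT  | position → other position  | same side, by the side owner       |

A held weight affords 5 moves, a hung weight 4, so out-degrees lie in
[16, 20] and the total directed edge count is 168,000.  Every move has a
legal reverse, so the edge relation is symmetric, and the side-swap
mirror map is a graph automorphism.  Targets are the 24 states with
exactly one weight hung per side and equal integer torque
(mass × position); torque comparison is integer-only, so the predicate is
exact.  No balanced configuration suspends the 500 g weight.

The 84-code raw-action vocabulary is the mirror-collapse of the
actor-explicit move types: per weight, 1 pass + 4 hangs + 4 removes + 12
ordered shift pairs = 21 actor-relative codes, enumerated in that order
(code = 21·weight_index + offset + 1).  The original 1–84 coding is known only
up to its count, so any order-preserving bijection is equivalent; ours is
fixed and documented here for reproducibility.  Tagged tokens keep the
role and render as readable strings ("B hangs the 500 g weight at
position 2").

## Effectiveness indicators

State effectiveness `d_s` is the BFS distance (unit edge costs) from `s`
to the nearest target, computed multi-source from the target set over
reversed edges.  Transition effectiveness is `Δd = d_s − d_{s'}`; by
reversibility `|Δd| ≤ 1`, and from every non-target state at least one
move has `Δd = +1`.  Sequence re-representations:

* `raw` — tagged action strings (n-gram use) or collapsed ordinal codes
  1..84 (DTW use; deliberately ordinal, reproducing the practice the
  effectiveness encodings are meant to improve on);
* `delta` — `"A: 1"`-style tokens, or the numeric Δd series;
* `state-pair` — `"A: 2→1"`-style tokens, or the numeric *post-move* `d`
  series (the optimal solution reads `2, 1, 0`, omitting the initial 3).

Sequence summaries report length, mean Δd (which telescopes to
`(d_initial − d_final)/length`), the forward/still/backward proportions,
mean post-move `d`, and a success label.  Success defaults to *terminal
state is balanced*; because groups can leave a balanced state, an
"ever visited" rule is available as a flag.

### A discrepancy with the commonly reported state-space summary

This task is usually summarized as having intermediate distances spanning
1..5 and 16 realizable ordered `(d, d')` pair types (5 progressive /
6 neutral / 5 regressive).  Exhaustive computation on the state space
above contradicts this: the 96 states with all four weights
hung on one side at positions from which no hung weight can participate in
a balanced pair require 6 moves (shift the kept weight, remove two, and
remove/pass/hang the weight bound for the other side), giving max d = 6
and 19 realizable pairs.  The contradiction is not resolvable by modeling
choices: forbidding peg co-occupancy shrinks the state space below 10,000
yet still leaves d = 6 states, and enlarging the target set to arbitrary
torque-balanced configurations breaks the worked removal example above
(its Δ = −1 would become 0).  The package reports what
it computes; the two corresponding acceptance tests fail by design and
document this.

## n-gram chi-square selection

TF-ISF weights use the within-sequence term frequency, corpus size N and
sequence frequency sf: `(1 + log tf)·log(N/sf)` for tf ≥ 1, else 0;
natural log by default (base is configurable; it rescales χ² but not the
sign structure).  For each n-gram of one order and representation the 2×2
table holds its TF-ISF mass summed over successful vs failed sequences
against the aggregate mass of all other n-grams of the same order.  χ² is
computed on these continuous masses with expectations from the margins,
df = 1, no Yates correction; φ = √(χ²/T) with T the grand table total
(the alternative normalization by sequence count is not used); the
direction sign is `sign(O₁₁ − E₁₁)`.  BH correction runs per
representation × order family (statsmodels step-up); ranking ties are
broken lexicographically.  Zero-margin n-grams (e.g. tokens present in
every sequence, whose TF-ISF mass is identically zero) are skipped with a
warning rather than given an undefined statistic.

## DTW + K-medoids

DTW uses the classic unnormalized recurrence
`D(i,j) = |x_i − y_j| + min(D(i−1,j), D(i,j−1), D(i−1,j−1))`
("symmetric1"); a symmetric2 variant (diagonal cost doubled) is
selectable.  No warping window and no endpoint relaxation.  The inner
loop is numba-compiled; a 422-sequence matrix at typical lengths (~50)
takes seconds on one CPU.

PAM is the deterministic classic: BUILD (first medoid minimizes total
distance, then greedy maximum-gain additions), then repeated best
improving single swaps; all ties break toward the lowest index, so runs
are exactly reproducible.  PAM is a local search: on random tiny
instances it occasionally terminates in a 1-swap-optimal solution above
the exhaustive-enumeration optimum — the reference R implementation does
the same on such instances — and the test suite asserts exactly that
dichotomy.  The silhouette uses the standard (b−a)/max(a,b) with the
singleton-cluster value 0.  Calinski–Harabasz is not defined for a bare
distance matrix, so the package uses a documented medoid-based
generalization: W = Σ_c Σ_{i∈c} D[i, m_c]², B = Σ_c n_c·D[m_c, m*]² with
m* the global medoid, CH = (B/(k−1))/(W/(n−k)); degenerate W = 0 is
reported as +inf with a warning.  Reference analyses of this task relied on external-package defaults
that are not fully specified for either DTW or CH, so their empirical
index values are not comparable targets.

Two-cluster interpretation uses pooled-variance two-sided t-tests
(df = n₁+n₂−2) over per-sequence features — role-merged unigram
frequencies and the sequence summaries — with BH correction and pooled-SD
Cohen's d; zero-variance features are skipped with a warning.

## Simulator

The generator is a memoryless softmax walker: from state `s`,
`P(move) ∝ exp(θ·Δd)`.  θ = 0 is a uniform random walk (validated against
the absorbing-Markov-chain completion probability computed on the full
10,000-state chain); large θ follows a BFS-optimal path (3 steps).
Cohort defaults are 422 groups, θ ~ Normal(0.8, 0.5), and a 120-action
cap with absorption at the first balanced state; an optional
continue-with-probability rule models post-success activity.  Each cohort
uses one root seed with per-group child streams, so generation is
reproducible and parallelizable.  Completion rate rises steeply in θ and
saturates near θ ≈ 0.8 under the default cap; the monotonicity test grid
(−0.5, 0, 0.5) spans the unsaturated range.

What the simulator does *not* emulate: chat/communication, pauses and
timestamps, role negotiation, memory or strategy switching, and system
errors.  Passing tests on synthetic cohorts therefore demonstrates that
the pipeline recovers planted effectiveness structure — not that any
particular behavioral finding holds in empirical data.

## Fixture sizes and numerics

The test suite uses scaled-down cohorts (60-group two-component mixtures,
60-action cap) for the qualitative pipeline checks, 500 replicates per
grid point for θ-monotonicity (Wilson intervals at z = 2.576), 200
40-sequence null corpora for the FDR check, and exhaustive oracles for
DTW (all monotone warping paths, series length ≤ 4) and PAM (all medoid
subsets, n ≤ 8).  Distances and masses are float64 throughout; the only
tolerance-sensitive comparison is the PAM swap acceptance, which requires
improvement by more than 1e-12 to guarantee termination.

## Limitations

* Only this task instance is validated (weights, 4 positions,
  2 roles); the machinery is parameterized internally but untested beyond
  it.
* Effectiveness assumes unit-cost reversible transitions; tasks with
  irreversible or weighted moves need a different distance.
* The empirical dataset's on-disk schema is unknown; `read_log` expects
  the documented CSV/JSON-lines schema, and adapting an external export
  means mapping it to those columns.
* Shortest-path effectiveness undervalues exploration-heavy strategies;
  the indicators measure distance-to-goal, not information gained.
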