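# Methods

## Model and assumptions

The gym is an open-shop-style scheduling model: `M` patients (jobs) visit
`N` single-skill robots (machines) over a session of `G` discrete time
steps, each patient using each robot at most once, for one uninterrupted
block, with no preemption. Skills map one-to-one to robots, improvement
is a deterministic, perfectly known function of cumulative training time,
and all patients are present for the whole session. These are deliberate
simplifications: real gyms involve noisy skill estimates, stochastic
learning, motivation and fatigue, none of which are modeled here.

The skill curve is the hyperbola

    S(d) = c1 (c2 + c4 (d + u)) / (c2 + c4 (d + u) + c3),

gain(d) = S(d) − S(0). For any valid parameters the marginal gain of the
d-th step is `c1 c3 c4 / ((w + c3)(w + c4 + c3))` with
`w = c2 + c4 u + c4 (d−1)`, strictly positive and strictly decreasing
when `c1, c4 > 0` — the concavity every algorithm here leans on.
Durations are integers only; fractional steps are rejected because the
schedule's decision variables are integral. `u` is treated as an opaque
calibration constant (prior steps + 1); cross-session carryover is not
modeled. The equal-curve preset is `c1=100, c2=1, c3=10, c4=1, u=1`.

### Tunable parameters

| parameter | units | default | why |
|---|---|---|---|
| `G` | time steps | scenario-specific (7 or 12 in the standard suite) | a step stands for any fixed slot length (e.g. 5–10 min) |
| `H` | time steps | `G` | last allowed start; `H = G` lets a patient train a single final step |
| `exit_time` | time steps | 0 (1 in the "with exit time" variants) | strap/unstrap overhead after leaving a robot |
| curve `c1..c4, u` | skill units / dimensionless | equal-curve preset | `c1` = scale ceiling; `c2, c3` set shape and initial skill; `c4` = advance per step |
| optimizer `budget` | candidate evaluations | 20 000 (40 000 in the acceptance script) | see "Search", below |

## Interval and gap semantics

Blocks are 1-based inclusive `[start, end]`. A successor on the same
robot, or the same patient's next robot, must start at
`end + e + 1` or later, where `e` is the exit time of the robot being
vacated. The alternative reading `start >= end + e` (which a literal
transcription of the disjunctive inequalities would give) permits
same-step double occupancy at `e = 0`, so the `+1` form is used
everywhere — it is the semantics under which the 12-step/exit-1
switch-halfway schedule splits 6+5 and totals 261.4, matching the
reference evaluation row by row. The exit after a patient's final block
costs nothing (there is no successor to block).

## Baselines

Both baselines resolve contention greedily: repeatedly give a free robot
to the (patient, robot) pair with the largest gain, ties broken by lower
patient then lower robot index. *Best robot only* assigns
`min(M, N)` patients for the whole session. *Switch halfway* splits the
session into `d1 = ceil((G − e)/2)` and `d2 = G − e − d1` (longer half
first; this split is what reproduces the reference totals for 7, 12 and
12-with-exit sessions). In the second half the tie-break is cyclic —
each patient prefers the robot just after their first-half robot — so a
group of identical curves rotates cleanly instead of deadlocking the
last patient on their own robot; a patient who cannot get a second robot
keeps the first for the whole session. For unequal curves robots are
ranked by gain over the half actually assigned (not the full session).

## Optimizer

### Encodings

Two equivalent MINLP variable encodings are provided with independent
constraint checkers, used both as search move spaces and to verify
formulation equivalence:

- *time-indexed*: a 0/1 start indicator per (robot, patient, step ≤ H)
  plus an integer duration per pair; the checker enforces one start per
  pair, per-step start uniqueness, the horizon cap, and exclusion
  windows `[start, start + d + e − 1]` per patient and per robot.
- *disjunctive*: integer start/end per pair, activation booleans, and
  patient/robot precedence booleans deactivating big-V disjunctions;
  `V = G + max exit + 1`, the smallest constant that disables a
  disjunct over the variable ranges.

A schedule passes one checker iff it passes the other and iff the
interval validator accepts it (property-tested on random block sets).

### Repair heuristic

Candidates pass through a repair scan iterated to a fixed point:
*pull-forward* moves a block to the earliest start its predecessors
allow, and *extend* lengthens a block when both its patient and robot
would otherwise idle. Repair never lowers total gain, preserves
feasibility, and is idempotent. Under the fairness objectives the
repaired candidate can score worse (repair is a total-gain heuristic),
so the search keeps whichever of the raw/repaired candidate scores
better; under the total objective they coincide.

### Bounds

`upper_bound` is the minimum of two provable over-estimates:

1. **Solo bound** — the sum over patients of each patient's exact
   maximum alone in the gym (`max_individual_gain`): enumerate robot
   subsets, charge the exit time of every visited robot except the last
   (so the largest-exit robot goes last), and allocate the remaining
   integer budget by largest marginal gain — exact for concave gains
   under the laminar budget constraints.
2. **Capacity bound** — the exact optimum of the relaxation that keeps
   only the per-robot and per-patient totals ≤ G, dropping exits and
   interval structure. Solved as a min-cost flow with one unit-capacity
   arc per (pair, k-th training step) priced at the negated marginal
   gain; a greedy spend of robot capacity is *not* guaranteed to sit
   above the true optimum, which is why the relaxation is solved
   exactly (plus 1e-6 to absorb integer cost scaling).

Both bounds are tight on the 5-patient/5-robot equal-curve scenarios,
which is what lets the search terminate with a proof of optimality
there.

### Search

`optimize` is an anytime, seed-deterministic search. Incumbents start
from the two baselines (so the result never falls below either, at any
budget, including budget 0). Iterations run in fixed cycles of 400:

- the first iteration of the run tries *rotation constructions* —
  synchronized phases whose lengths come from the patients' solo-optimal
  duration splits, patient `j` taking robot `j+i (mod N)` in phase `i` —
  plus a greedy build from scratch; for identical curves the rotation
  realizes every patient's solo optimum simultaneously and meets the
  solo bound exactly;
- each later cycle starts with a ruin-and-recreate kick (drop a random
  block subset, a whole patient, or a whole robot from the incumbent,
  then re-insert unit blocks by best marginal gain with randomized
  tie-breaks and repair);
- the remaining iterations are simulated annealing over
  encoding-native moves — integer start/end/activation edits
  (disjunctive) or start-indicator toggles and duration adjustments
  (time-indexed) — plus two composite moves both encodings share:
  swapping two blocks' intervals, and shifting the boundary between a
  block and its successor (needed because repair's pull-forward cancels
  any plain "delay" edit). Temperature decays from 3 to 0.02 skill
  units within each cycle.

The search stops early once the incumbent is within 1e-5 of the upper
bound (total objective only). Budgets are candidate-evaluation counts,
not comparable to any external solver's iterations; with the defaults a
5x5x12 instance takes a few seconds on one core. Because the proposal
stream for a given seed does not depend on the budget, the result value
is nondecreasing in the budget.

### Brute-force oracle

`brute_force_optimal` enumerates semi-active schedules (every block at
the earliest start its predecessors allow — any feasible schedule
left-shifts into this form without changing durations or value) by
chronological block appends, pruned with a cached per-patient optimistic
completion bound. It is guarded to 3 patients, 3 robots and 6 steps by
default; the caps are parameters, and larger instances raise a size
error pointing to `optimize`. The oracle shares no code path with the
search and is used to verify it on every instance under the cap.

## Group objectives

- `total`: summed gain (the default).
- `variance_penalized`: total − m · Var(per-patient gains). The variance
  is interpreted as a single session-level penalty on the distribution
  of per-patient gains, computed as the population variance (divide by
  M); the choice is configurable (`variance_ddof`).
- `relative_to_max`: Σ_j [gain_j − m_j (1 − gain_j / max_j)], where
  `max_j` is patient j's exact solo maximum (computed automatically by
  `optimize` when not supplied). `max_j = 0` with a positive penalty is
  rejected.

## Synthetic patient groups

`GroupSpec` draws a pool of 42 curves with `c2 ∈ [0.01, 100]` and
`c3 ∈ [5, 1000]`, then deals `M·N` of them to pairs without replacement,
deterministically per seed. Both ranges span 3–4 decades, so the draw is
log-uniform by default (a uniform draw would almost never produce small
`c2` or `c3`; a `log_uniform=False` flag restores uniform sampling).
One pool is drawn per group seed. The generator emulates heterogeneous
impairment levels and learning rates only through curve shape; it does
not model noise, forgetting, inter-skill transfer, or within-session
nonstationarity — so passing tests say nothing about robustness to
mis-estimated curves on real patients. Because the random pools used in
the original evaluation are not available, random-group runs assert only
the ordering property (optimized ≥ both baselines); their absolute
totals are seed-specific.

## Numerical choices and degenerate inputs

- All skill arithmetic is double precision; comparisons against totals
  printed at one decimal use absolute tolerance 0.05.
- `c2 = 0` and `c4 = 0` are valid curves (`c4 = 0` gives zero gain
  everywhere) to support degenerate fixtures; the study ranges are
  enforced only by the group generator.
- Empty schedules, zero-patient and zero-robot scenarios are all legal
  and yield zero gain; `H < G` is honored by every component, including
  the solo-optimum allocator.
- Ties in greedy steps break by lowest index (plus the cyclic rule in
  the switch-halfway second half), making baselines fully deterministic;
  the optimizer's randomness comes only from its integer seed.

## Problem sizes used in the shipped runs

The test suite exercises gyms up to 6 patients x 7 robots x 12 steps and
oracle instances up to 3x3x6; the acceptance script runs the nine
standard scenarios with a 40 000-candidate budget per optimizer cell
(seconds per cell on one core, since tight bounds let the three 5P5R
cells and all exit-time cells terminate at proven optimality almost
immediately). The scaling experiment records wall-clock durations for
illustration only; they are hardware-dependent and asserted nowhere.

## Known limitations

- The search is a metaheuristic: away from instances where a bound is
  tight (or the oracle applies), results carry no optimality proof —
  only the guarantees of dominating both baselines and monotonicity in
  budget.
- The capacity bound ignores exit times and can be loose when exits are
  large or `M > N`.
- The rotation construction assumes one shared phase template per run;
  with strongly heterogeneous curves its seed value degrades gracefully
  but the kicks and annealing must do more of the work.
- Fairness objectives are optimized over the same move space as total
  gain; extreme penalty weights can make the empty schedule a local
  optimum's neighbor, so budgets should be generous there.
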