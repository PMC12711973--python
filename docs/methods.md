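# Methods

`orsched` schedules elective inpatient and outpatient surgeries that share
operating-room (OR) blocks, under three sources of uncertainty: surgery
durations, the arrival of emergency patients, and no-shows.  The framework
has two phases — *advance scheduling* (which patients, which block) and
*allocation scheduling* (sequence and start times within each block) —
joined by an overall objective and validated by a discrete-event evaluator.

## Problem setting and notation

A master surgery schedule (MSS) assigns each OR block `(j, k)` (room `j`,
day `k`) to one specialty, with ordinary duration `L` (default 480 min) and
an overtime cap `H` (default 60 min).  Each waiting-list patient `i` has an
estimated operating time (EOT) `mu_i`, duration SD `sigma_i`, no-show rate
`r_i`, a scheduling cost `c_i^sched` (the penalty for leaving them on the
list another horizon), a cancellation cost `c_i^canc`, and a per-minute
direct-waiting cost `c_i^wait`.  Unit costs `c^g` (idle) and `c^h`
(overtime) price the facility side; defaults are `c^g = 1/9`, `c^h = 1/6`
(a patient-centered preference; `c^g = c^h = 1/3` is the facility-centered
alternative).

Real-time policies: surgeries run in the planned order, never start before
their scheduled time, and a present patient is operated iff their expected
completion (actual start + EOT) does not exceed `L + H`; otherwise they are
cancelled (postponed to the next horizon).  No-shows are discovered at the
scheduled moment and consume no time.  An arriving emergency is inserted in
its assigned room as soon as possible: immediately if the room is idle,
else right after the surgery in progress.

## Random variables

Per scenario: elective durations `rho_i` are lognormal with *arithmetic*
mean `mu_i` and SD `sigma_i` (log-scale parameters by moment matching:
`s^2 = ln(1 + (sigma/mu)^2)`, `m = ln mu - s^2/2`); presence `theta_i` is
Bernoulli(`1 - r_i`); each block independently receives one emergency with
probability `p_em = 0.2`, of lognormal duration (mean 93 min, SD 60 min)
truncated at 240 min, arriving uniformly over `[0, L]`.  Truncation is by
rejection, not clipping: clipping would put an atom at 240 min and bias the
shape, whereas rejection keeps the conditional density.  Arrival times are
`tau = 0` whenever no emergency occurs.

Random streams are keyed by `(seed, kind, patient-or-block index)` through
`numpy` `SeedSequence`s, so adding a patient or block never perturbs the
draws of the others, and every stage of a run shares one sample for paired
comparisons.

## Phase 1 — chance-constrained assignment

One integer program per specialty selects patients and blocks.  The
objective is hierarchical: the top level is the total scheduling cost of
patients left unscheduled; the bottom level, scaled by `b1` so it can never
overturn a top-level difference of one cost grid step (`Delta = 10`), mixes
three patient-mix proxies weighted by `beta = (beta1, beta2, beta3)`:
the largest per-block sum of cancellation costs, the largest per-block sum
of waiting costs, and the total absolute deviation of per-block expected
utilization from the specialty mean.  The balancing constants are
`m_s = floor(max L / min mu)`, `b2 = max c^canc / max c^wait`,
`b3 = m_s max c^canc / (|B_s| max L / 2)`, `b1 = Delta / (1 + m_s max c^canc)`.

Robustness: per block, `P[delta + sum_i theta_i rho_i x_i > L + H] <= alpha`.
The probability is replaced by its Monte Carlo estimate over the shared
scenario sample and linearized exactly with one overload indicator per
(block, scenario) and a budget of `floor(alpha |S|)` violated scenarios —
the strict reading of the constraint.  Each indicator's big-M is the
tightest valid constant, `max(0, scenario load with everyone assigned -
(L + H))`; scenarios that cannot overload generate no indicator.  The
utilization proxy uses the sample-average load, a linear expression of the
assignment variables, with standard positive/negative split variables for
the absolute values; the cancellation/waiting proxies are epigraph
variables.  Because a zero `beta` component leaves its epigraph variable
unpinned, every reported proxy, utilization and overload frequency is
recomputed from the assignment itself after solving, never read from the
solver's auxiliaries.

## Phase 2 — sequencing and timing

Given a block's patient set, the first stage chooses a sequence (binaries
`o_ii'`) and scheduled starts `t_i` (first start 0, planned completions
within `L`); the second stage evaluates the realized timeline per scenario.
The recourse cost is
`c^h h + c^g g + sum_i c_i^canc (1 - y_i) + sum_i c_i^wait a_i`
(overtime, idle, cancellations, direct waiting).

### The recourse kernel

The evaluation keeps two clocks: the *auxiliary* timeline (the
counterfactual without the emergency) and the *actual* one.  The emergency
is inserted after the elective whose auxiliary start is the last not
exceeding the arrival `tau`; it starts at `max(tau, actual completion of
what precedes it)`.  Cancellation and waiting are read off the actual
timeline.  Cancelled patients and no-shows consume no time but their
decision moment propagates as a floor on later starts (this "collapse"
convention never delays anyone beyond what the planned starts already
imply).  The block completion `C` is the maximum over executed electives'
completions and the emergency completion; overtime is `max(0, C - L)` and
idle time satisfies the conservation identity
`max(L, C) = executed work + delta + g` exactly.

The kernel exists twice: a scalar reference implementation returning the
full per-patient timeline, and a vectorized version (arrays across
scenarios) used as the genetic algorithm's fitness and the re-evaluator of
every solver's output; the two are bit-compatible by test.

### SAA and N-fold SAA

The expectation is replaced by a sample average, giving one extensive-form
MILP with a copy of the second-stage variables per scenario.  Indicator
couplings are linearized with per-scenario big-M
`M = L + H + sum_i rho_i theta_i + delta`:

* actual and auxiliary starts are pinned *exactly* to
  `max(predecessor completion, t_i)` using a selector binary per patient and
  scenario for the upper side of the max — a one-sided bound would let the
  solver buy cancellations (or avoid them) with fictitious delays;
* similarly the pre-emergency idle `z` is forced to
  `max(0, tau - completion)` with an idle-at-arrival selector binary;
* the insertion position `e` needs only its forward implications: together
  with `sum e = 1` and the monotonicity of auxiliary starts along the
  sequence they pin it uniquely;
* one valid inequality beyond the textbook constraint set,
  `C >= c_i - M(1 - e_i)`, keeps the emergency completion in `C` when the
  insertion point is a cancelled or absent patient; without it the model
  would under-report overtime in exactly that corner and disagree with the
  simulation;
* strict inequalities (cancellation threshold, insertion interval) carry an
  `eps = 1e-6` min tolerance; with continuous durations and arrivals the
  ambiguous band has measure zero, and the oracle-equivalence tests draw
  from continuous distributions so ties cannot occur.

With the first stage frozen, the model is the per-scenario second-stage
oracle; the test suite checks the algorithmic kernel against it on hundreds
of random cases to 1e-6.

The plain SAA is exact but explodes with block size (the per-scenario
binaries dominate); it is expected — and tested — to time out *gracefully*
on large blocks, returning an explicit status rather than raising.  The
N-fold variant (default `N = 10`) solves the SAA on each of `N` disjoint
folds of the sample, giving each an equal share of the block's time budget,
re-evaluates every fold's schedule on the *full* sample with the recourse
kernel (never the fold objective, which would be optimistically biased),
and keeps the best; ties break at the lowest fold index.  When `N` does not
divide `|S|`, the last fold absorbs the remainder.

### BRKGA

A chromosome of `2|I|` unit-interval genes encodes a schedule: the first
half orders the surgeries (ascending gene value; ties — possible only for
hand-written chromosomes — break by patient id), the second half splits the
planned idle time `G = L - sum mu_i` into slacks proportionally to the
gene values at each *position* of the decoded sequence, the last position's
share becoming the end-of-block slack.  All-zero timing genes decode to a
back-to-back schedule.  Every chromosome decodes to a feasible schedule, so
the whole population explores the search space; decoded slacks always sum
to `G` exactly.

Evolution uses the standard elitist scheme with the tuned defaults:
population 50, elite fraction 1/4, mutant fraction 1/5, per-gene elite
inheritance probability 1/2 (elites copied verbatim, mutants drawn fresh,
offspring from one uniformly chosen elite and one non-elite parent).
Fitness is the vectorized sample-average recourse cost; termination is by
generation count or wall-clock budget, returning the best individual ever
seen, so the best fitness is non-increasing across generations and runs are
reproducible under a fixed seed.

## Overall objective and sweep

`Z = sum of unscheduled patients' scheduling costs + sum over blocks of the
full-sample expected recourse cost`; the advance proxies are excluded (they
only steer the mix).  The default sweep grid is
`alpha in {0.05, 0.10, 0.15}` crossed with the three unit `beta` vectors;
per block the allocation method is chosen by size — N-fold SAA up to 6
patients, BRKGA beyond — reflecting where each method wins, and is
overridable.  Configuration failures are recorded per record and the sweep
continues.  Patient-mix reporting uses the Gini impurity
`GI = 1 - (n_in/|I|)^2 - (n_out/|I|)^2` per block, averaged and normalized
by its upper bound at `n_in = f_in |I|`.

## Discrete-event evaluation

Bernoulli mode replays the optimization-stage model (at most one emergency
per block) through the recourse kernel on shared random streams, so
optimizer and evaluator agree to the last bit.  Poisson mode relaxes the
assumption: per block the emergency count is Poisson with the same mean
`p_em`, arrivals uniform and served in order, FIFO at the room (an
emergency arriving while another runs waits for it).  Emergencies are never
cancelled and may run past `L + H` (the cap governs electives only);
their overtime is charged.  On identical schedules the Poisson mean cost
dominates the Bernoulli one up to sampling error — extra emergencies cannot
help — and emergency waits lengthen, which is exactly the stress test the
one-emergency assumption needs.

## Synthetic instances

The generator emulates a five-specialty operating theater
(cardiology, gastroenterology, gynecology, orthopedics, urology) with the
case-mix weights 14.32 / 18.76 / 30.43 / 15.90 / 20.59 % and 28 procedure
groups whose lognormal mixture parameters (frequency, mean, SD per
specialty) are built in.  Printed mixture frequencies carry rounding slack
(one specialty sums to 0.999), so they are renormalized per specialty.
Groups come in two variability designs (duration CV about 0.151 and 0.202);
the classifier threshold sits at the midpoint, CV < 0.175 = low
variability.  A patient's group is drawn from the specialty mixture; the
outpatient label has probability 0.7 given low CV and 0.3 given high CV.
No-show rates are 0.08 (inpatients) and 0.24 (outpatients); scheduling
costs are uniform on {10, 20, ..., 100}; cancellation costs are 4x the
scheduling cost for inpatients and 2x for outpatients; waiting costs per
minute are uniform on [1/360, 1/36] for inpatients and [1/180, 1/18] for
outpatients (outpatients wait dearer on average, inpatients cancel dearer).

The default MSS spans 9 ORs and 26 blocks over a five-day week; the
per-OR specialty multiset is fixed (e.g. OR 3 is pure cardiology, OR 9 has
no Monday block) while day placement within an OR uses the earliest
weekdays; both are fully overridable through the instance file.

What the generator does **not** model: correlated durations, time-varying
no-show behavior, ward/bed and staffing constraints, week-over-week
rolling horizons, and the low-volume general-medicine stream.  Passing
tests therefore demonstrate correctness of the optimization and evaluation
machinery under the stated stochastic model, not calibration to any
particular hospital.

## Numerical choices and problem sizes

MILPs are solved with HiGHS through `scipy.optimize.milp`; all models are
assembled sparsely.  Relative MIP gap defaults to 1e-6 (1e-9 floor in the
helper); time budgets default to 300 s per advance model and per block,
configurable.  Equality-style checks in tests use 1e-6 against MILP oracles
and 1e-9 for pure-arithmetic identities.  Test and example workloads are
scaled for a single desktop core: waiting lists of 25–100 patients,
scenario samples of 30–200 for optimization, 10^4–10^5 for Monte Carlo
parameter checks, and micro-instances (≤ 8 patients, ≤ 2 blocks, |S| = 50)
wherever an exhaustive oracle must enumerate the search space.

## Known limitations

* The extensive-form SAA is practical only for small blocks; this is a
  property of the formulation, reproduced rather than fixed here.
* The chance constraint is sampled, so feasibility is with respect to the
  training sample; out-of-sample overload probability can exceed `alpha`
  by sampling error.
* The `eps` tolerances make schedules whose realized times land exactly on
  a decision boundary formally infeasible in the MILP (measure-zero under
  the continuous distributions, but reachable with hand-crafted integer
  data).
* Advance models at low `alpha` on large instances may terminate at the
  time limit with a small proven gap; monotonicity checks in the tests
  account for the reported gaps.
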