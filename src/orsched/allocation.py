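"""Allocation scheduling: SAA and N-fold SAA for one OR block.

The sequencing + timing problem of a block is a two-stage stochastic
mixed-integer program: first-stage binaries o_ii' (i' immediately follows i)
and continuous scheduled starts t_i; the second stage evaluates, per
scenario, the realized timeline under the real-time policies (emergency
insertion, cancellation, no-show collapse) and its overtime / idle /
cancellation / waiting cost.  Here the expectation is replaced by a sample
average (SAA), yielding one extensive-form MILP with a copy of the
second-stage variables per scenario.

The implication / max / iff couplings of the second stage are linearized
with indicator binaries and per-scenario big-M constants
``M = L + H + sum_i rho_i theta_i + delta``:

* actual and auxiliary starts are pinned *exactly* to
  ``max(predecessor completion, t_i)`` via a selector binary per patient and
  scenario (both directions of the max), because the cancellation rule reads
  the actual start and would otherwise be gamed by slack starts;
* the emergency insertion position (Eq. coupling e with the auxiliary
  timeline) only needs its forward implications: together with
  ``sum_i e_i = 1`` and the monotonicity of auxiliary starts along the
  sequence they pin e uniquely;
* the pre-emergency idle z is forced to ``max(0, tau - completion)`` with an
  "idle at arrival" selector binary, not merely bounded, again to prevent
  the solver from buying cancellations with artificial idle time;
* the block completion C additionally satisfies ``C >= c_i - M(1 - e_i)``:
  the printed recourse constraints lose the emergency completion when the
  insertion point is a cancelled or absent patient, and this valid
  inequality restores exact agreement with the algorithmic recourse.

Strict inequalities (cancellation threshold, insertion interval) use an
``eps = 1e-6`` minute tolerance; with continuous durations and arrivals the
ambiguous band has measure zero.

The N-fold variant solves the SAA on each of N disjoint folds of the sample
(equal share of the time budget each), re-evaluates every fold's schedule on
the *full* sample with the algorithmic recourse, and keeps the best.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._milp import Model
from .instances import ORBlock, Patient
from .recourse import BlockSchedule, expected_cost
from .scenarios import ScenarioSample, partition_folds

EPS = 1e-6


class AllocationError(ValueError):
    pass


@dataclass(frozen=True)
class AllocationConfig:
    method: str = "nfold_saa"  # "saa" | "nfold_saa"
    n_folds: int = 10
    time_limit: float = 300.0  # seconds per block, split across folds
    mip_gap: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_folds < 1:
            raise AllocationError("n_folds must be >= 1")
        if self.method not in ("saa", "nfold_saa"):
            raise AllocationError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class AllocationSolution:
    schedule: BlockSchedule | None
    expected_cost: float | None  # full-sample re-evaluation via recourse
    status: str  # optimal | feasible | infeasible_within_limit
    objective: float | None = None  # solver objective on its own sample


@dataclass
class SaaMilp:
    """Extensive-form SAA model plus the index maps needed to decode it."""

    model: Model
    block: ORBlock
    patients: tuple[Patient, ...]
    o_idx: dict[tuple[int, int], int]
    t_idx: list[int]

    def decode(self, x: np.ndarray) -> BlockSchedule:
        n = len(self.patients)
        if n == 0:
            return BlockSchedule(block=self.block, patients=(), start_times=())
        succ = {}
        has_pred = set()
        for (i, j), col in self.o_idx.items():
            if x[col] > 0.5:
                succ[i] = j
                has_pred.add(j)
        first = next(i for i in range(n) if i not in has_pred)
        order = [first]
        while order[-1] in succ:
            order.append(succ[order[-1]])
        # repair solver round-off so the schedule passes strict validation
        t = []
        clock = 0.0
        for pos, i in enumerate(order):
            ti = 0.0 if pos == 0 else max(float(x[self.t_idx[i]]), clock)
            t.append(ti)
            clock = ti + self.patients[i].mean_duration
        overrun = t[-1] + self.patients[order[-1]].mean_duration - self.block.length
        if overrun > 0:
            if overrun > 1e-4:
                raise AllocationError("decoded schedule exceeds block length")
            # push starts back by the round-off overrun where slack allows
            for pos in range(n - 1, 0, -1):
                lo = t[pos - 1] + self.patients[order[pos - 1]].mean_duration
                t[pos] = max(lo, t[pos] - overrun)
        return BlockSchedule(
            block=self.block,
            patients=tuple(self.patients[i] for i in order),
            start_times=tuple(t),
        )


def build_saa_milp(
    block: ORBlock,
    patients: list[Patient] | tuple[Patient, ...],
    sample: ScenarioSample,
    c_idle: float,
    c_over: float,
    fixed_schedule: BlockSchedule | None = None,
) -> SaaMilp:
    """Assemble the extensive-form MILP.

    With ``fixed_schedule`` the first stage (o, t) is frozen to the given
    sequence and start times, turning the model into the per-scenario
    second-stage oracle used to validate the algorithmic recourse.
    """
    if len(sample) == 0:
        raise AllocationError("empty scenario sample")
    patients = tuple(patients)
    n = len(patients)
    L, H = block.length, block.max_overtime
    mdl = Model()

    o_idx: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                o_idx[(i, j)] = mdl.add_binary()
    t_idx = [
        mdl.add_var(0.0, max(0.0, L - patients[i].mean_duration)) for i in range(n)
    ]

    if fixed_schedule is not None:
        pos_of = {p.id: k for k, p in enumerate(fixed_schedule.patients)}
        order = sorted(range(n), key=lambda i: pos_of[patients[i].id])
        arcs = {(order[k], order[k + 1]) for k in range(n - 1)}
        for (i, j), col in o_idx.items():
            val = 1.0 if (i, j) in arcs else 0.0
            mdl._lb[col] = mdl._ub[col] = val
        for i in range(n):
            ti = float(fixed_schedule.start_times[pos_of[patients[i].id]])
            mdl._lb[t_idx[i]] = mdl._ub[t_idx[i]] = ti
    else:
        # planned completion within L; forces the first patient to t = 0
        for i in range(n):
            coeffs = {t_idx[i]: 1.0}
            for j in range(n):
                if j != i:
                    coeffs[o_idx[(j, i)]] = -(L - patients[i].mean_duration)
            mdl.add_constraint(coeffs, ub=0.0)
        # start-time consistency with the sequence, big-M = L
        for (i, j), col in o_idx.items():
            mdl.add_constraint(
                {t_idx[i]: 1.0, t_idx[j]: -1.0, col: L},
                ub=L - patients[i].mean_duration,
            )
        if n:
            mdl.add_constraint(
                {col: 1.0 for col in o_idx.values()}, lb=n - 1, ub=n - 1
            )
        for i in range(n):  # path structure: at most one successor/predecessor
            if n > 1:
                mdl.add_constraint(
                    {o_idx[(i, j)]: 1.0 for j in range(n) if j != i}, ub=1.0
                )
                mdl.add_constraint(
                    {o_idx[(j, i)]: 1.0 for j in range(n) if j != i}, ub=1.0
                )

    S = len(sample)
    for scen in sample:
        delta = scen.em_duration[block.key]
        tau = scen.em_arrival[block.key]
        theta = [scen.presence[p.id] for p in patients]
        rho = [scen.rot[p.id] for p in patients]
        d = [rho[i] * theta[i] for i in range(n)]  # realized duration if kept
        M = L + H + sum(d) + delta + 1.0

        q = [mdl.add_var(0.0, M) for _ in range(n)]
        qa = [mdl.add_var(0.0, M) for _ in range(n)]
        c = [mdl.add_var(0.0, M) for _ in range(n)]
        ca = [mdl.add_var(0.0, M) for _ in range(n)]
        z = [mdl.add_var(0.0, M) for _ in range(n)]
        a = [mdl.add_var(0.0, M) for _ in range(n)]
        y = [mdl.add_binary() for _ in range(n)]
        e = [mdl.add_binary() for _ in range(n)]
        v = [mdl.add_binary() for _ in range(n)]
        w = [mdl.add_binary() for _ in range(n)]
        wa = [mdl.add_binary() for _ in range(n)]
        Cv = mdl.add_var(0.0, M)
        h = mdl.add_var(0.0, M)
        g = mdl.add_var(0.0, M)

        for i in range(n):
            # q_i, qa_i = 0 for the first patient; >= t_i otherwise
            coeffs_q = {q[i]: 1.0}
            coeffs_qa = {qa[i]: 1.0}
            for j in range(n):
                if j != i:
                    coeffs_q[o_idx[(j, i)]] = -M
                    coeffs_qa[o_idx[(j, i)]] = -M
            mdl.add_constraint(coeffs_q, ub=0.0)
            mdl.add_constraint(coeffs_qa, ub=0.0)
            mdl.add_constraint({q[i]: 1.0, t_idx[i]: -1.0}, lb=0.0)
            mdl.add_constraint({qa[i]: 1.0, t_idx[i]: -1.0}, lb=0.0)
            # upper side of the max: either the scheduled start ...
            mdl.add_constraint({q[i]: 1.0, t_idx[i]: -1.0, w[i]: -M}, ub=0.0)
            mdl.add_constraint({qa[i]: 1.0, t_idx[i]: -1.0, wa[i]: -M}, ub=0.0)

        for (i, j), col in o_idx.items():
            # ... or the predecessor completion (lower and upper side)
            mdl.add_constraint({q[j]: 1.0, c[i]: -1.0, col: -M}, lb=-M)
            mdl.add_constraint({qa[j]: 1.0, ca[i]: -1.0, col: -M}, lb=-M)
            mdl.add_constraint({q[j]: 1.0, c[i]: -1.0, col: M, w[j]: M}, ub=2 * M)
            mdl.add_constraint({qa[j]: 1.0, ca[i]: -1.0, col: M, wa[j]: M}, ub=2 * M)
            # insertion interval: e_i = 1 and o_ij = 1 => qa_j > tau
            mdl.add_constraint(
                {qa[j]: 1.0, e[i]: -M, col: -M}, lb=tau + EPS - 2 * M
            )

        for i in range(n):
            # completions (auxiliary excludes the emergency)
            mdl.add_constraint(
                {c[i]: 1.0, q[i]: -1.0, y[i]: -d[i], z[i]: -1.0, e[i]: -delta},
                lb=0.0,
                ub=0.0,
            )
            mdl.add_constraint(
                {ca[i]: 1.0, qa[i]: -1.0, y[i]: -d[i]}, lb=0.0, ub=0.0
            )
            # block completion C
            mdl.add_constraint(
                {
                    Cv: 1.0,
                    q[i]: -float(theta[i]),
                    y[i]: -(theta[i] * rho[i]) - M,
                    z[i]: -1.0,
                    e[i]: -delta,
                },
                lb=-M,
            )
            mdl.add_constraint({Cv: 1.0, c[i]: -1.0, e[i]: -M}, lb=-M)
            # emergency insertion point and idle before the emergency
            mdl.add_constraint({z[i]: 1.0, e[i]: -M}, ub=0.0)
            mdl.add_constraint({qa[i]: 1.0, e[i]: M}, ub=tau + M)
            mdl.add_constraint(
                {z[i]: 1.0, q[i]: 1.0, y[i]: d[i], e[i]: -M}, lb=tau - M
            )
            mdl.add_constraint(
                {z[i]: 1.0, q[i]: 1.0, y[i]: d[i], v[i]: M, e[i]: M},
                ub=tau + 2 * M,
            )
            mdl.add_constraint({z[i]: 1.0, v[i]: -M}, ub=0.0)
            mdl.add_constraint(
                {q[i]: 1.0, y[i]: d[i], v[i]: M, e[i]: M}, ub=tau + 2 * M
            )
            # cancellation policy (expected completion vs L + H)
            if theta[i] == 1:
                mu_i = patients[i].mean_duration
                mdl.add_constraint({q[i]: 1.0, y[i]: M}, ub=L + H - mu_i + M)
                mdl.add_constraint({q[i]: 1.0, y[i]: M}, lb=L + H - mu_i + EPS)
                mdl.add_constraint(
                    {a[i]: 1.0, q[i]: -1.0, t_idx[i]: 1.0, y[i]: -M}, lb=-M
                )
            else:
                mdl._lb[y[i]] = 1.0  # no-shows are never "cancelled"

        if n:
            mdl.add_constraint({e[i]: 1.0 for i in range(n)}, lb=1.0, ub=1.0)
        mdl.add_constraint({Cv: 1.0}, lb=tau + delta)
        mdl.add_constraint({h: 1.0, Cv: -1.0}, lb=-L)
        work = {g: 1.0}
        for i in range(n):
            work[y[i]] = d[i]
        mdl.add_constraint(dict(work), lb=L - delta)
        work[Cv] = -1.0
        mdl.add_constraint(work, lb=-delta)

        # per-scenario share of the sample-average objective
        mdl.set_objective(h, c_over / S)
        mdl.set_objective(g, c_idle / S)
        for i in range(n):
            mdl.set_objective(y[i], -patients[i].c_canc / S)
            mdl.set_objective(a[i], patients[i].c_wait / S)
            mdl.obj_constant += patients[i].c_canc / S

    return SaaMilp(model=mdl, block=block, patients=patients, o_idx=o_idx, t_idx=t_idx)


def second_stage_cost(
    schedule: BlockSchedule,
    scenario,
    c_idle: float,
    c_over: float,
    time_limit: float = 60.0,
) -> float:
    """Optimal objective of the second-stage MILP for a fixed schedule and
    one scenario — the optimization oracle the simulation must reproduce."""
    sample = ScenarioSample(scenarios=(scenario,), seed=0)
    built = build_saa_milp(
        schedule.block,
        schedule.patients,
        sample,
        c_idle,
        c_over,
        fixed_schedule=schedule,
    )
    res = built.model.solve(time_limit=time_limit)
    if res.status not in ("optimal", "feasible") or res.objective is None:
        raise AllocationError(f"second-stage oracle failed: {res.status}")
    return res.objective


def solve_saa(
    block: ORBlock,
    patients: list[Patient] | tuple[Patient, ...],
    sample: ScenarioSample,
    c_idle: float,
    c_over: float,
    config: AllocationConfig | None = None,
    eval_sample: ScenarioSample | None = None,
) -> AllocationSolution:
    """Solve the extensive-form SAA on ``sample``.

    ``eval_sample`` (default: ``sample``) is the set on which the returned
    ``expected_cost`` is recomputed with the algorithmic recourse.  Times out
    gracefully: no incumbent within the limit yields status
    ``infeasible_within_limit``, never an exception.
    """
    config = config or AllocationConfig(method="saa")
    eval_sample = eval_sample or sample
    built = build_saa_milp(block, patients, sample, c_idle, c_over)
    res = built.model.solve(time_limit=config.time_limit, mip_gap=config.mip_gap)
    if res.x is None:
        return AllocationSolution(
            schedule=None, expected_cost=None, status="infeasible_within_limit"
        )
    schedule = built.decode(res.x)
    cost = expected_cost(schedule, eval_sample, c_idle, c_over)
    return AllocationSolution(
        schedule=schedule,
        expected_cost=cost,
        status=res.status,
        objective=res.objective,
    )


def solve_nfold_saa(
    block: ORBlock,
    patients: list[Patient] | tuple[Patient, ...],
    sample: ScenarioSample,
    c_idle: float,
    c_over: float,
    config: AllocationConfig | None = None,
) -> AllocationSolution:
    """N-fold SAA: solve per fold, re-evaluate on the full sample, keep the
    best (ties broken by lowest fold index).  Folds with no incumbent are
    skipped; if every fold fails the status is ``infeasible_within_limit``."""
    config = config or AllocationConfig()
    folds = partition_folds(sample, min(config.n_folds, len(sample)))
    per_fold = AllocationConfig(
        method="saa",
        time_limit=config.time_limit / len(folds),
        mip_gap=config.mip_gap,
    )
    best: AllocationSolution | None = None
    for fold in folds:
        sol = solve_saa(
            block, patients, fold, c_idle, c_over, per_fold, eval_sample=sample
        )
        if sol.schedule is None:
            continue
        if best is None or sol.expected_cost < best.expected_cost:
            best = sol
    if best is None:
        return AllocationSolution(
            schedule=None, expected_cost=None, status="infeasible_within_limit"
        )
    return best


def enumerate_permutation_costs(
    block: ORBlock,
    patients: list[Patient] | tuple[Patient, ...],
    sample: ScenarioSample,
    c_idle: float,
    c_over: float,
) -> dict[tuple[int, ...], float]:
    """Expected recourse cost of every permutation with back-to-back timing.

    Brute-force oracle for small blocks; keys are patient-id tuples in
    sequence order.
    """
    patients = tuple(patients)
    out: dict[tuple[int, ...], float] = {}
    for perm in itertools.permutations(range(len(patients))):
        seq = tuple(patients[i] for i in perm)
        t, clock = [], 0.0
        for p in seq:
            t.append(clock)
            clock += p.mean_duration
        if clock > block.length + 1e-9:
            continue
        sched = BlockSchedule(block=block, patients=seq, start_times=tuple(t))
        out[tuple(p.id for p in seq)] = expected_cost(sched, sample, c_idle, c_over)
    return out
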