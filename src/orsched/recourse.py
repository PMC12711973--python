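"""Realized timeline and cost of one OR-block schedule under one scenario.

This is the algorithmic implementation of the second-stage (recourse)
problem: given the sequence and scheduled start times of a block and a joint
realization of durations, no-shows and the block's (possible) emergency
surgery, it applies the operating theater's real-time policies and returns
the realized timeline with its cost

    c^h * overtime + c^g * idle + sum c_i^canc (1 - y_i) + sum c_i^wait a_i.

Policies, in sequence order:

* A surgery starts at the later of its scheduled time and the completion of
  whatever precedes it on the actual timeline; starts are never anticipated.
* The emergency (if any) is inserted after the elective whose start on the
  *auxiliary* timeline (the counterfactual without the emergency) is the
  last not exceeding the arrival tau; it begins at tau if the room is idle,
  else at the completion of the surgery in progress.
* A present patient is cancelled iff their expected completion (actual start
  + EOT) would exceed L + H; no-shows and cancellations consume no time but
  their decision moment propagates as a floor on later starts.
* Direct waiting a_i = actual start - scheduled start, for executed present
  patients only.

The same kernel, vectorized across scenarios, is the fitness function of the
genetic algorithm and the re-evaluator of the N-fold SAA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instances import ORBlock, Patient
from .scenarios import Scenario, ScenarioSample


class RecourseError(ValueError):
    pass


@dataclass(frozen=True)
class BlockSchedule:
    """Sequence and scheduled start times for one OR block.

    ``patients`` is in sequence order; ``start_times`` are minutes from block
    start.  Feasibility (first start 0, no planned overlap, planned
    completion within L) is validated on construction.
    """

    block: ORBlock
    patients: tuple[Patient, ...]
    start_times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.start_times
        ps = self.patients
        if len(t) != len(ps):
            raise RecourseError("start_times and patients length mismatch")
        if not ps:
            return
        eps = 1e-9
        if abs(t[0]) > eps:
            raise RecourseError("first scheduled start must be 0")
        for a in range(len(ps) - 1):
            if t[a] + ps[a].mean_duration > t[a + 1] + eps:
                raise RecourseError(
                    f"planned completion of position {a} overlaps position {a + 1}"
                )
        last = len(ps) - 1
        if t[last] + ps[last].mean_duration > self.block.length + eps:
            raise RecourseError("planned completion exceeds block length")

    @property
    def size(self) -> int:
        return len(self.patients)


@dataclass(frozen=True)
class ScenarioOutcome:
    """Realized timeline of one block under one scenario (sequence order)."""

    aux_start: tuple[float, ...]
    aux_completion: tuple[float, ...]
    actual_start: tuple[float, ...]
    actual_completion: tuple[float, ...]
    executed: tuple[int, ...]  # y_i (1 also for no-shows)
    present: tuple[int, ...]  # theta_i
    waiting: tuple[float, ...]  # a_i, minutes
    pre_em_idle: tuple[float, ...]  # z_i
    emergency_after: tuple[int, ...]  # e_i
    em_start: float  # nan if no emergency in the block
    last_completion: float  # C
    overtime: float  # h
    idle: float  # g
    over_cost: float
    idle_cost: float
    canc_cost: float
    wait_cost: float

    @property
    def cost(self) -> float:
        return self.over_cost + self.idle_cost + self.canc_cost + self.wait_cost


def simulate_block(
    schedule: BlockSchedule,
    scenario: Scenario,
    c_idle: float,
    c_over: float,
) -> ScenarioOutcome:
    """Reference (scalar) implementation of the recourse evaluation."""
    block = schedule.block
    L, H = block.length, block.max_overtime
    for p in schedule.patients:
        if p.id not in scenario.rot or p.id not in scenario.presence:
            raise RecourseError(f"scenario lacks realizations for patient {p.id}")
    if block.key not in scenario.em_duration:
        raise RecourseError(f"scenario lacks emergency data for block {block.key}")
    delta = scenario.em_duration[block.key]
    tau = scenario.em_arrival[block.key]

    n = schedule.size
    aux_q = [0.0] * n
    aux_c = [0.0] * n
    act_q = [0.0] * n
    act_c = [0.0] * n
    y = [1] * n
    theta = [scenario.presence[p.id] for p in schedule.patients]
    a = [0.0] * n
    z = [0.0] * n
    e = [0] * n
    em_start = float("nan")
    C = 0.0

    aux_clock = 0.0
    act_clock = 0.0
    inserted = delta <= 0.0
    for p in range(n):
        pat = schedule.patients[p]
        t_p = schedule.start_times[p]
        aux_q[p] = max(aux_clock, t_p)
        if not inserted and tau < aux_q[p]:
            # emergency goes after the previous elective in sequence
            e[p - 1] = 1 if p > 0 else 0  # p == 0 unreachable: aux_q[0] == 0 <= tau
            em_start = max(tau, act_clock)
            z[p - 1] = max(0.0, tau - act_clock)
            act_clock = em_start + delta
            C = max(C, act_clock)
            inserted = True
        act_q[p] = max(act_clock, t_p)
        if theta[p] == 1 and act_q[p] + pat.mean_duration > L + H:
            y[p] = 0  # cancelled: postponed to the next planning horizon
        dur = scenario.rot[pat.id] if (theta[p] == 1 and y[p] == 1) else 0.0
        aux_c[p] = aux_q[p] + dur
        act_c[p] = act_q[p] + dur
        if theta[p] == 1 and y[p] == 1:
            a[p] = act_q[p] - t_p
            C = max(C, act_c[p])
        aux_clock = aux_c[p]
        act_clock = act_c[p]

    if not inserted:
        em_start = max(tau, act_clock)
        if n:
            e[n - 1] = 1
            z[n - 1] = max(0.0, tau - act_clock)
        C = max(C, em_start + delta)

    exec_work = sum(
        scenario.rot[pat.id]
        for p, pat in enumerate(schedule.patients)
        if theta[p] == 1 and y[p] == 1
    )
    h = max(0.0, C - L)
    g = max(L, C) - exec_work - delta
    canc = sum(
        pat.c_canc
        for p, pat in enumerate(schedule.patients)
        if theta[p] == 1 and y[p] == 0
    )
    wait = sum(pat.c_wait * a[p] for p, pat in enumerate(schedule.patients))
    return ScenarioOutcome(
        aux_start=tuple(aux_q),
        aux_completion=tuple(aux_c),
        actual_start=tuple(act_q),
        actual_completion=tuple(act_c),
        executed=tuple(y),
        present=tuple(theta),
        waiting=tuple(a),
        pre_em_idle=tuple(z),
        emergency_after=tuple(e),
        em_start=em_start,
        last_completion=C,
        overtime=h,
        idle=g,
        over_cost=c_over * h,
        idle_cost=c_idle * g,
        canc_cost=canc,
        wait_cost=wait,
    )


def emergency_wait(outcome: ScenarioOutcome, scenario: Scenario, block: ORBlock) -> float:
    """Waiting time of the block's emergency patient: actual start - arrival.

    Zero when the room was idle at arrival.  Raises if the scenario has no
    emergency in this block.
    """
    if scenario.em_duration.get(block.key, 0.0) <= 0.0:
        raise RecourseError(f"no emergency surgery in block {block.key}")
    return outcome.em_start - scenario.em_arrival[block.key]


# ---------------------------------------------------------------------------
# vectorized evaluation across a scenario sample


@dataclass(frozen=True)
class BlockScenarioData:
    """Scenario realizations for one block's patient set, as dense arrays.

    Shapes: ``rot`` and ``presence`` are (n_patients, n_scenarios) in the
    *given patient order*; ``em_duration`` / ``em_arrival`` are
    (n_scenarios,).  Decouples the (fixed) sample from the (varying)
    sequence, so genetic-algorithm fitness never re-extracts scenario data.
    """

    block: ORBlock
    patients: tuple[Patient, ...]
    rot: np.ndarray
    presence: np.ndarray
    em_duration: np.ndarray
    em_arrival: np.ndarray
    c_idle: float
    c_over: float

    @classmethod
    def from_sample(
        cls,
        block: ORBlock,
        patients: list[Patient] | tuple[Patient, ...],
        sample: ScenarioSample,
        c_idle: float,
        c_over: float,
    ) -> "BlockScenarioData":
        patients = tuple(patients)
        rot = np.array([[sc.rot[p.id] for sc in sample] for p in patients])
        pres = np.array([[sc.presence[p.id] for sc in sample] for p in patients])
        dl = np.array([sc.em_duration[block.key] for sc in sample])
        ta = np.array([sc.em_arrival[block.key] for sc in sample])
        if rot.size == 0:
            rot = rot.reshape(len(patients), len(sample))
            pres = pres.reshape(len(patients), len(sample))
        return cls(
            block=block,
            patients=patients,
            rot=rot,
            presence=pres,
            em_duration=dl,
            em_arrival=ta,
            c_idle=c_idle,
            c_over=c_over,
        )

    @property
    def n_scenarios(self) -> int:
        return self.em_duration.shape[0]


def batch_costs(
    data: BlockScenarioData,
    order: np.ndarray,
    start_times: np.ndarray,
) -> np.ndarray:
    """Recourse cost of the schedule (order, t) in every scenario at once.

    ``order`` holds indices into ``data.patients`` in sequence order;
    ``start_times`` are the scheduled starts for those positions.  Identical
    semantics to :func:`simulate_block`, vectorized across scenarios.
    """
    L = data.block.length
    H = data.block.max_overtime
    S = data.n_scenarios
    delta = data.em_duration
    tau = data.em_arrival

    aux_c = np.zeros(S)
    act_c = np.zeros(S)
    C = np.zeros(S)
    exec_work = np.zeros(S)
    canc_cost = np.zeros(S)
    wait_cost = np.zeros(S)
    inserted = delta <= 0.0

    for pos, idx in enumerate(order):
        pat = data.patients[idx]
        t_p = start_times[pos]
        aux_q = np.maximum(aux_c, t_p)
        m = (~inserted) & (tau < aux_q)
        if m.any():
            em_start = np.maximum(tau[m], act_c[m])
            act_c[m] = em_start + delta[m]
            C[m] = np.maximum(C[m], act_c[m])
            inserted |= m
        act_q = np.maximum(act_c, t_p)
        present = data.presence[idx] == 1
        cancelled = present & (act_q + pat.mean_duration > L + H)
        executed = present & ~cancelled
        dur = np.where(executed, data.rot[idx], 0.0)
        aux_c = aux_q + dur
        act_c = act_q + dur
        C = np.where(executed, np.maximum(C, act_c), C)
        exec_work += dur
        canc_cost += np.where(cancelled, pat.c_canc, 0.0)
        wait_cost += np.where(executed, pat.c_wait * (act_q - t_p), 0.0)

    m = ~inserted
    if m.any():
        em_start = np.maximum(tau[m], act_c[m])
        C[m] = np.maximum(C[m], em_start + delta[m])

    h = np.maximum(0.0, C - L)
    g = np.maximum(L, C) - exec_work - delta
    return data.c_over * h + data.c_idle * g + canc_cost + wait_cost


def expected_cost(
    schedule: BlockSchedule,
    sample: ScenarioSample,
    c_idle: float,
    c_over: float,
) -> float:
    """Sample-average recourse cost of a block schedule."""
    if len(sample) == 0:
        raise RecourseError("empty scenario sample")
    data = BlockScenarioData.from_sample(
        schedule.block, schedule.patients, sample, c_idle, c_over
    )
    order = np.arange(len(schedule.patients))
    return float(
        np.mean(batch_costs(data, order, np.asarray(schedule.start_times)))
    )
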