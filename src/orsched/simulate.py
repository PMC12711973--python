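"""Discrete-event evaluation of complete weekly schedules.

Two emergency-generation modes:

* ``bernoulli`` — at most one emergency per block, exactly the modeling
  assumption of the optimization stage; evaluation goes through the
  recourse kernel scenario by scenario, so optimizer and simulator agree
  bitwise on shared random streams.
* ``poisson`` — relaxes the assumption: the number of emergencies per block
  is Poisson with the same mean p_em, each inserted as soon as possible in
  arrival order (FIFO at the room: an emergency arriving while another is
  in progress waits for it).  Elective policies (no anticipation,
  cancellation against L + H, no-show collapse) are identical to the
  recourse kernel.  Emergencies are never cancelled; work past the block
  end accrues overtime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instances import ProblemInstance
from .recourse import BlockSchedule, emergency_wait, simulate_block
from .scenarios import sample_poisson_emergencies, sample_scenarios


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationReport:
    """Scenario-mean performance of a weekly schedule."""

    mode: str
    n_scenarios: int
    objective: float  # mean recourse cost per scenario (all blocks)
    over_cost: float
    idle_cost: float
    canc_cost: float
    wait_cost: float
    emergency_wait: float  # minutes, mean over emergency patients
    inpatient: dict[str, float]
    outpatient: dict[str, float]

    def __post_init__(self) -> None:
        total = self.over_cost + self.idle_cost + self.canc_cost + self.wait_cost
        if abs(total - self.objective) > 1e-9:
            raise SimulationError("cost components do not sum to the objective")


def _poisson_block(
    schedule: BlockSchedule,
    rot: dict[int, float],
    presence: dict[int, int],
    emergencies: list[tuple[float, float]],
    c_idle: float,
    c_over: float,
) -> tuple[float, float, float, float, list[float], list[int], list[float], list[int]]:
    """One block, one scenario, any number of emergencies (arrival order)."""
    block = schedule.block
    L, H = block.length, block.max_overtime
    pending = list(emergencies)  # sorted by arrival
    busy_until = 0.0
    C = 0.0
    exec_work = 0.0
    em_total = sum(d for _, d in pending)
    canc = wait = 0.0
    waits: list[float] = []
    em_waits: list[float] = []
    y: list[int] = []
    theta: list[int] = []

    def flush(before: float | None) -> None:
        nonlocal busy_until, C
        while pending:
            tau, dur = pending[0]
            limit = before if before is not None else float("inf")
            if tau >= limit:
                return
            start = max(tau, busy_until)
            em_waits.append(start - tau)
            busy_until = start + dur
            C = max(C, busy_until)
            pending.pop(0)

    for pos, pat in enumerate(schedule.patients):
        t_p = schedule.start_times[pos]
        while True:
            s = max(busy_until, t_p)
            if pending and pending[0][0] < s:
                flush(s)
            else:
                break
        present = presence[pat.id]
        theta.append(present)
        if present and s + pat.mean_duration > L + H:
            y.append(0)
            canc += pat.c_canc
            waits.append(0.0)
            busy_until = s  # decision moment floors later starts
        elif present:
            y.append(1)
            busy_until = s + rot[pat.id]
            exec_work += rot[pat.id]
            C = max(C, busy_until)
            waits.append(s - t_p)
            wait += pat.c_wait * (s - t_p)
        else:  # no-show collapses to the decision moment
            y.append(1)
            waits.append(0.0)
            busy_until = s
    flush(None)
    h = max(0.0, C - L)
    g = max(L, C) - exec_work - em_total
    cost_over = c_over * h
    cost_idle = c_idle * g
    return cost_over, cost_idle, canc, wait, waits, y, em_waits, theta


def evaluate_schedule(
    schedules: dict[tuple[int, str], BlockSchedule],
    instance: ProblemInstance,
    n: int,
    mode: str = "bernoulli",
    seed: int = 0,
) -> EvaluationReport:
    """Monte Carlo evaluation of a weekly schedule over ``n`` scenarios."""
    if mode not in ("bernoulli", "poisson"):
        raise SimulationError(f"unknown mode {mode!r}")
    if n < 1:
        raise SimulationError("need at least one scenario")
    cfg = instance.config
    scheduled = [p for s in schedules.values() for p in s.patients]
    sample = sample_scenarios(instance, n, seed=seed)

    over = idle = canc = wait = 0.0
    em_waits: list[float] = []
    cls: dict[str, dict[str, list[float]]] = {
        "inpatient": {"start": [], "wait": [], "cancelled": []},
        "outpatient": {"start": [], "wait": [], "cancelled": []},
    }
    for pat in scheduled:
        for key, sched in schedules.items():
            if pat in sched.patients:
                pos = sched.patients.index(pat)
                cls[pat.patient_type]["start"].append(sched.start_times[pos])
                break

    if mode == "bernoulli":
        for sc in sample:
            for key, sched in schedules.items():
                out = simulate_block(sched, sc, cfg.c_idle, cfg.c_over)
                over += out.over_cost
                idle += out.idle_cost
                canc += out.canc_cost
                wait += out.wait_cost
                if sc.em_duration[key] > 0:
                    em_waits.append(emergency_wait(out, sc, sched.block))
                for pos, pat in enumerate(sched.patients):
                    rec = cls[pat.patient_type]
                    if out.present[pos]:
                        rec["cancelled"].append(1.0 - out.executed[pos])
                        if out.executed[pos]:
                            rec["wait"].append(out.waiting[pos])
    else:
        for key, sched in schedules.items():
            ems = sample_poisson_emergencies(instance, sched.block, n, seed=seed)
            for w, sc in enumerate(sample):
                co, ci, cc, cw, waits, y, ew, theta = _poisson_block(
                    sched, sc.rot, sc.presence, ems[w], cfg.c_idle, cfg.c_over
                )
                over += co
                idle += ci
                canc += cc
                wait += cw
                em_waits.extend(ew)
                for pos, pat in enumerate(sched.patients):
                    rec = cls[pat.patient_type]
                    if theta[pos]:
                        rec["cancelled"].append(1.0 - y[pos])
                        if y[pos]:
                            rec["wait"].append(waits[pos])

    def summary(rec: dict[str, list[float]]) -> dict[str, float]:
        if not rec["start"]:
            return {"present": 0.0}
        return {
            "present": 1.0,
            "mean_scheduled_start": float(np.mean(rec["start"])),
            "mean_wait": float(np.mean(rec["wait"])) if rec["wait"] else 0.0,
            "cancellation_probability": (
                float(np.mean(rec["cancelled"])) if rec["cancelled"] else 0.0
            ),
        }

    return EvaluationReport(
        mode=mode,
        n_scenarios=n,
        objective=(over + idle + canc + wait) / n,
        over_cost=over / n,
        idle_cost=idle / n,
        canc_cost=canc / n,
        wait_cost=wait / n,
        emergency_wait=float(np.mean(em_waits)) if em_waits else 0.0,
        inpatient=summary(cls["inpatient"]),
        outpatient=summary(cls["outpatient"]),
    )


def class_metrics(
    schedules: dict[tuple[int, str], BlockSchedule],
    report: EvaluationReport,
) -> dict[str, dict[str, float]]:
    """Per-class summaries (scheduled start, direct wait, cancellation)."""
    return {"inpatient": report.inpatient, "outpatient": report.outpatient}
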