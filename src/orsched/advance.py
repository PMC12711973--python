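"""Advance scheduling: chance-constrained assignment of patients to blocks.

One model per specialty selects patients from the waiting list and assigns
them to that specialty's OR blocks.  The objective is hierarchical: the top
level minimizes the total scheduling cost of patients left unscheduled; the
bottom level — scaled by b1 so it can never override the top level — mixes
three patient-mix proxies weighted by beta:

* Gamma_canc: the maximum per-block sum of cancellation costs,
* Gamma_wait: the maximum per-block sum of waiting costs,
* Gamma_time: total absolute deviation of per-block expected utilization
  from the specialty mean.

Robustness comes from a per-block chance constraint: the probability that
realized load (present patients' durations plus the emergency) exceeds
L + H must not exceed alpha.  The probability is replaced by its Monte Carlo
estimate over a scenario sample and linearized exactly with one overload
indicator per (block, scenario) and a budget of floor(alpha |S|) violated
scenarios; the big-M of each indicator is the tightest valid constant
max(0, scenario load excess when everyone is scheduled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._milp import Model
from .instances import ORBlock, Patient, ProblemInstance
from .scenarios import ScenarioSample


class AdvanceError(ValueError):
    pass


@dataclass(frozen=True)
class AdvanceConfig:
    alpha: float = 0.1
    beta: tuple[float, float, float] = (0.0, 0.0, 1.0)
    time_limit: float = 300.0
    mip_gap: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise AdvanceError("alpha must lie in (0, 1)")
        if any(b < 0 or b > 1 for b in self.beta) or abs(sum(self.beta) - 1) > 1e-9:
            raise AdvanceError("beta must be nonnegative with unit 1-norm")


@dataclass(frozen=True)
class HierarchyCoefficients:
    """Scaling constants that enforce the objective hierarchy.

    m_s bounds the patients per block; b2 and b3 bring the three proxies to
    a common order of magnitude (each normalized by its worst case); b1
    keeps the whole proxy term below one scheduling-cost grid step.
    """

    m_s: int
    b1: float
    b2: float
    b3: float


def hierarchy_coefficients(
    patients: list[Patient],
    blocks: list[ORBlock],
    delta_sched: float = 10.0,
) -> HierarchyCoefficients:
    if not patients or not blocks:
        raise AdvanceError("need at least one patient and one block")
    max_L = max(b.length for b in blocks)
    min_mu = min(p.mean_duration for p in patients)
    max_canc = max(p.c_canc for p in patients)
    max_wait = max(p.c_wait for p in patients)
    if max_wait <= 0:
        raise AdvanceError("maximum waiting cost must be positive")
    m_s = math.floor(max_L / min_mu)
    b2 = max_canc / max_wait
    b3 = (m_s * max_canc) / (len(blocks) * max_L / 2.0)
    b1 = delta_sched / (1.0 + m_s * max_canc)
    return HierarchyCoefficients(m_s=m_s, b1=b1, b2=b2, b3=b3)


@dataclass(frozen=True)
class AdvanceSolution:
    specialty: str
    assignment: dict[int, tuple[int, str]]  # patient id -> (or_id, day)
    objective: float
    total_sched_cost: float  # scheduling cost of *unscheduled* patients
    proxy_canc: float
    proxy_wait: float
    proxy_time: float
    mean_utilization: float
    block_utilization: dict[tuple[int, str], float]
    overload_freq: dict[tuple[int, str], float]  # training-sample P_jk
    gap: float | None
    status: str

    def patients_in_block(self, key: tuple[int, str]) -> list[int]:
        return [pid for pid, b in self.assignment.items() if b == key]


def _scenario_loads(
    patients: list[Patient], blocks: list[ORBlock], sample: ScenarioSample
) -> tuple[np.ndarray, np.ndarray]:
    """(theta*rho) per (patient, scenario) and delta per (block, scenario)."""
    tr = np.array(
        [[sc.presence[p.id] * sc.rot[p.id] for sc in sample] for p in patients]
    )
    dl = np.array([[sc.em_duration[b.key] for sc in sample] for b in blocks])
    return tr, dl


def build_advance_milp(
    patients: list[Patient],
    blocks: list[ORBlock],
    sample: ScenarioSample,
    config: AdvanceConfig,
    delta_sched: float = 10.0,
) -> tuple[Model, dict[tuple[int, int], int]]:
    """Assemble the assignment MILP; returns (model, x index map)."""
    if len(sample) == 0:
        raise AdvanceError("empty scenario sample")
    specs = {p.specialty for p in patients}
    if len(specs) > 1:
        raise AdvanceError(f"patients span multiple specialties: {sorted(specs)}")
    mdl = Model()
    nP, nB, S = len(patients), len(blocks), len(sample)
    coef = hierarchy_coefficients(patients, blocks, delta_sched)
    b1, b2, b3 = coef.b1, coef.b2, coef.b3
    beta1, beta2, beta3 = config.beta

    x = {(i, j): mdl.add_binary() for i in range(nP) for j in range(nB)}
    # top level: scheduling cost of unscheduled patients
    mdl.obj_constant = sum(p.c_sched for p in patients)
    for (i, j), col in x.items():
        mdl.set_objective(col, -patients[i].c_sched)

    for i in range(nP):  # each patient in at most one block
        mdl.add_constraint({x[(i, j)]: 1.0 for j in range(nB)}, ub=1.0)
    for j, b in enumerate(blocks):  # deterministic capacity on EOTs
        mdl.add_constraint(
            {x[(i, j)]: patients[i].mean_duration for i in range(nP)}, ub=b.length
        )

    # Monte Carlo chance constraints
    tr, dl = _scenario_loads(patients, blocks, sample)
    budget = math.floor(config.alpha * S)
    for j, b in enumerate(blocks):
        cap = b.length + b.max_overtime
        v_cols = []
        for w in range(S):
            excess = dl[j, w] + tr[:, w].sum() - cap
            if excess <= 0:
                continue  # cannot overload even with everyone scheduled
            v = mdl.add_binary()
            v_cols.append(v)
            coeffs = {x[(i, j)]: tr[i, w] for i in range(nP)}
            coeffs[v] = -excess  # tightest valid big-M
            mdl.add_constraint(coeffs, ub=cap - dl[j, w])
        if len(v_cols) > budget:
            mdl.add_constraint({v: 1.0 for v in v_cols}, ub=float(budget))

    # proxies (epigraph forms; exact because minimized when weighted)
    gamma_c = mdl.add_var(0.0)
    gamma_w = mdl.add_var(0.0)
    for j in range(nB):
        mdl.add_constraint(
            {**{x[(i, j)]: patients[i].c_canc for i in range(nP)}, gamma_c: -1.0},
            ub=0.0,
        )
        mdl.add_constraint(
            {**{x[(i, j)]: patients[i].c_wait for i in range(nP)}, gamma_w: -1.0},
            ub=0.0,
        )
    # utilization balance: |u_jk - mean| via split variables; u_jk is the
    # sample-average load, a linear expression of x
    mean_tr = tr.mean(axis=1)  # E[theta_i rho_i] per patient
    mean_dl = dl.mean(axis=1)  # E[delta] per block
    dev_pos = [mdl.add_var(0.0) for _ in range(nB)]
    dev_neg = [mdl.add_var(0.0) for _ in range(nB)]
    for j in range(nB):
        coeffs: dict[int, float] = {}
        for i in range(nP):
            coeffs[x[(i, j)]] = mean_tr[i]
            for j2 in range(nB):
                coeffs[x[(i, j2)]] = coeffs.get(x[(i, j2)], 0.0) - mean_tr[i] / nB
        coeffs[dev_pos[j]] = -1.0
        coeffs[dev_neg[j]] = 1.0
        rhs = -(mean_dl[j] - mean_dl.mean())
        mdl.add_constraint(coeffs, lb=rhs, ub=rhs)

    mdl.set_objective(gamma_c, b1 * beta1)
    mdl.set_objective(gamma_w, b1 * beta2 * b2)
    for j in range(nB):
        mdl.set_objective(dev_pos[j], b1 * beta3 * b3)
        mdl.set_objective(dev_neg[j], b1 * beta3 * b3)
    return mdl, x


def solve_advance(
    instance: ProblemInstance,
    specialty: str,
    sample: ScenarioSample,
    config: AdvanceConfig | None = None,
) -> AdvanceSolution:
    """Solve the assignment model for one specialty.

    All reported quantities (proxies, utilization, overload frequencies) are
    recomputed from the assignment itself, independently of the solver's
    auxiliary variables.
    """
    config = config or AdvanceConfig()
    patients = instance.patients_of(specialty)
    blocks = instance.mss.blocks_for(specialty)
    if not blocks:
        raise AdvanceError(f"no OR block assigned to specialty {specialty}")
    if not patients:
        raise AdvanceError(f"no waiting-list patient of specialty {specialty}")
    mdl, x = build_advance_milp(
        patients, blocks, sample, config, instance.config.delta_sched
    )
    res = mdl.solve(time_limit=config.time_limit, mip_gap=config.mip_gap)
    if res.x is None:
        raise AdvanceError(f"advance model not solved: status {res.status}")

    assignment: dict[int, tuple[int, str]] = {}
    for (i, j), col in x.items():
        if res.x[col] > 0.5:
            assignment[patients[i].id] = blocks[j].key

    tr, dl = _scenario_loads(patients, blocks, sample)
    S = len(sample)
    util: dict[tuple[int, str], float] = {}
    overload: dict[tuple[int, str], float] = {}
    canc_sums, wait_sums = [], []
    for j, b in enumerate(blocks):
        rows = [i for i, p in enumerate(patients) if assignment.get(p.id) == b.key]
        load = dl[j] + (tr[rows].sum(axis=0) if rows else 0.0)
        util[b.key] = float(np.mean(load))
        overload[b.key] = float(np.mean(load > b.length + b.max_overtime))
        canc_sums.append(sum(patients[i].c_canc for i in rows))
        wait_sums.append(sum(patients[i].c_wait for i in rows))
    u_mean = float(np.mean(list(util.values())))
    proxy_time = float(sum(abs(u - u_mean) for u in util.values()))
    unsched = sum(p.c_sched for p in patients if p.id not in assignment)
    return AdvanceSolution(
        specialty=specialty,
        assignment=assignment,
        objective=float(res.objective),
        total_sched_cost=unsched,
        proxy_canc=max(canc_sums),
        proxy_wait=max(wait_sums),
        proxy_time=proxy_time,
        mean_utilization=u_mean,
        block_utilization=util,
        overload_freq=overload,
        gap=res.gap,
        status=res.status,
    )


def audit_chance_constraints(
    solution: AdvanceSolution, alpha: float, sample_size: int
) -> bool:
    """Independent post-hoc check of the per-block overload budget."""
    budget = math.floor(alpha * sample_size) / sample_size
    return all(f <= budget + 1e-12 for f in solution.overload_freq.values())
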