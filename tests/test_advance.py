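"""Chance-constrained assignment: hierarchy, oracle equivalence, audits."""

import itertools
import math

import numpy as np
import pytest

from orsched.advance import (
    AdvanceConfig,
    AdvanceError,
    audit_chance_constraints,
    hierarchy_coefficients,
    solve_advance,
)
from orsched.instances import (
    InstanceConfig,
    MasterSurgerySchedule,
    ProblemInstance,
)
from orsched.scenarios import ScenarioSample, sample_scenarios
from tests.conftest import (
    degenerate_scenario,
    make_block,
    make_patient,
    single_specialty_instance,
)


class TestHierarchyCoefficients:
    def test_worked_values(self):
        patients = [
            make_patient(0, mu=20.0, c_sched=100.0, patient_type="inpatient",
                         c_wait=1.0 / 18.0),
            make_patient(1, mu=150.0, c_sched=10.0, c_wait=1.0 / 300.0),
        ]
        blocks = [make_block(1), make_block(2, day="Tue")]
        coef = hierarchy_coefficients(patients, blocks, delta_sched=10.0)
        assert coef.m_s == 24  # floor(480 / 20)
        assert coef.b2 == pytest.approx(7200.0)  # 400 / (1/18)
        assert coef.b1 == pytest.approx(10.0 / 9601.0)  # 10 / (1 + 24*400)
        assert coef.b3 == pytest.approx(24 * 400.0 / (2 * 480.0 / 2))

    def test_proxy_term_below_one_grid_step(self):
        """b1 caps the whole bottom level below delta_sched: the proxies can
        never overturn a scheduling-cost difference."""
        patients = [make_patient(i, mu=30.0, patient_type="inpatient",
                                 c_sched=100.0, c_wait=1.0 / 36.0)
                    for i in range(4)]
        blocks = [make_block()]
        coef = hierarchy_coefficients(patients, blocks)
        worst_proxy = coef.m_s * 400.0  # all slots filled with max c_canc
        assert coef.b1 * worst_proxy < 10.0

    def test_zero_wait_cost_rejected(self):
        import dataclasses

        p = dataclasses.replace(make_patient(0), c_wait=0.0)
        with pytest.raises(AdvanceError, match="waiting cost"):
            hierarchy_coefficients([p], [make_block()])

    def test_config_validation(self):
        with pytest.raises(AdvanceError):
            AdvanceConfig(alpha=0.0)
        with pytest.raises(AdvanceError):
            AdvanceConfig(beta=(0.5, 0.5, 0.5))


def brute_force_advance(patients, blocks, sample, config, delta_sched=10.0):
    """Exhaustive enumeration over all patient->block assignments."""
    from orsched.advance import hierarchy_coefficients as hc

    coef = hc(patients, blocks, delta_sched)
    S = len(sample)
    budget = math.floor(config.alpha * S)
    tr = np.array([[sc.presence[p.id] * sc.rot[p.id] for sc in sample]
                   for p in patients])
    dl = np.array([[sc.em_duration[b.key] for sc in sample] for b in blocks])
    nB = len(blocks)
    best = np.inf
    for assign in itertools.product(range(nB + 1), repeat=len(patients)):
        ok = True
        loads_mu = [0.0] * nB
        members: list[list[int]] = [[] for _ in range(nB)]
        for i, a in enumerate(assign):
            if a:
                loads_mu[a - 1] += patients[i].mean_duration
                members[a - 1].append(i)
        for j, b in enumerate(blocks):
            if loads_mu[j] > b.length + 1e-12:
                ok = False
                break
            load = dl[j] + (tr[members[j]].sum(axis=0) if members[j] else 0.0)
            if (load > b.length + b.max_overtime).sum() > budget:
                ok = False
                break
        if not ok:
            continue
        unsched = sum(p.c_sched for i, p in enumerate(patients) if not assign[i])
        canc = max(sum(patients[i].c_canc for i in m) for m in members)
        wait = max(sum(patients[i].c_wait for i in m) for m in members)
        util = [float(dl[j].mean() + sum(tr[i].mean() for i in members[j]))
                for j in range(nB)]
        dev = sum(abs(u - np.mean(util)) for u in util)
        b1, b2, b3 = coef.b1, coef.b2, coef.b3
        beta1, beta2, beta3 = config.beta
        obj = unsched + b1 * (beta1 * canc + beta2 * b2 * wait + beta3 * b3 * dev)
        best = min(best, obj)
    return best


def micro_instance(seed, n_patients=6, lengths=(480.0, 480.0)):
    blocks = [make_block(or_id=k + 1, day="Mon" if k == 0 else "Tue",
                         length=L) for k, L in enumerate(lengths)]
    return single_specialty_instance(n_patients, blocks, seed=seed)


def test_milp_matches_enumeration_on_micro_instance():
    inst = micro_instance(seed=61)
    sample = sample_scenarios(inst, 50, seed=1)
    cfg = AdvanceConfig(alpha=0.1, beta=(0.2, 0.3, 0.5), time_limit=60)
    sols = [
        solve_advance(inst, inst.waiting_list[0].specialty, sample, cfg)
    ]
    assert sols[0].status == "optimal"
    best = brute_force_advance(
        list(inst.waiting_list), list(inst.mss.blocks), sample, cfg
    )
    assert sols[0].objective == pytest.approx(best, abs=1e-6)


def test_alpha_relaxation_never_increases_objective():
    inst = micro_instance(seed=67, n_patients=8)
    sample = sample_scenarios(inst, 60, seed=2)
    spec = inst.waiting_list[0].specialty
    objs = {}
    for alpha in (0.05, 0.15):
        sol = solve_advance(inst, spec, sample,
                            AdvanceConfig(alpha=alpha, time_limit=60))
        assert sol.status == "optimal"
        objs[alpha] = sol.objective
    assert objs[0.15] <= objs[0.05] + 1e-9


def _unique_cost_instance():
    """Distinct powers-of-two scheduling costs make the min-cost scheduled
    set unique, so beta cannot change which patients are scheduled."""
    import dataclasses

    blocks = [make_block(1, length=300.0), make_block(2, day="Tue", length=300.0)]
    inst = single_specialty_instance(6, blocks, seed=71)
    wl = []
    for k, p in enumerate(inst.waiting_list):
        wl.append(dataclasses.replace(
            p, c_sched=10.0 * 2**k,
            c_canc=(4.0 if p.patient_type == "inpatient" else 2.0) * 10.0 * 2**k,
            mean_duration=100.0, sd_duration=20.0,
        ))
    return dataclasses.replace(inst, waiting_list=tuple(wl))


def test_beta_does_not_change_scheduled_cost_when_unique():
    inst = _unique_cost_instance()
    sample = sample_scenarios(inst, 50, seed=3)
    spec = inst.waiting_list[0].specialty
    sols = {}
    for beta in ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)):
        sol = solve_advance(inst, spec, sample,
                            AdvanceConfig(alpha=0.1, beta=beta, time_limit=60))
        assert sol.status == "optimal"
        sols[beta] = sol
    costs = {s.total_sched_cost for s in sols.values()}
    assert len(costs) == 1

    # proxy effectiveness: enabling proxy k minimizes proxy k
    canc = {b: s.proxy_canc for b, s in sols.items()}
    wait = {b: s.proxy_wait for b, s in sols.items()}
    time_ = {b: s.proxy_time for b, s in sols.items()}
    assert canc[(1.0, 0.0, 0.0)] <= min(canc.values()) + 1e-9
    assert wait[(0.0, 1.0, 0.0)] <= min(wait.values()) + 1e-9
    assert time_[(0.0, 0.0, 1.0)] <= min(time_.values()) + 1e-9


def test_chance_constraint_audit(instance40):
    sample = sample_scenarios(instance40, 80, seed=4)
    for spec in ("CARDIO", "URO"):
        sol = solve_advance(instance40, spec, sample,
                            AdvanceConfig(alpha=0.1, time_limit=120))
        assert audit_chance_constraints(sol, 0.1, 80)
        # recompute independently of the solution object as well
        by_id = {p.id: p for p in instance40.waiting_list}
        for b in instance40.mss.blocks_for(spec):
            pids = sol.patients_in_block(b.key)
            over = 0
            for sc in sample:
                load = sc.em_duration[b.key] + sum(
                    sc.presence[pid] * sc.rot[pid] for pid in pids
                )
                over += load > b.length + b.max_overtime
            assert over / len(sample) <= 0.1


def test_degenerate_sample_makes_chance_constraints_vacuous():
    """With rho == mu, no emergencies and no no-shows, any assignment obeying
    the deterministic capacity also satisfies the chance constraints."""
    inst = micro_instance(seed=73, n_patients=5)
    sc = degenerate_scenario(list(inst.waiting_list), list(inst.mss.blocks))
    sample = ScenarioSample(scenarios=(sc,) * 10, seed=0)
    cfg = AdvanceConfig(alpha=0.05, beta=(1.0, 0.0, 0.0), time_limit=60)
    sol = solve_advance(inst, inst.waiting_list[0].specialty, sample, cfg)
    assert sol.status == "optimal"
    assert all(f == 0.0 for f in sol.overload_freq.values())
    best = brute_force_advance(
        list(inst.waiting_list), list(inst.mss.blocks), sample, cfg
    )
    assert sol.objective == pytest.approx(best, abs=1e-6)


def test_missing_block_or_patients_raise(instance40):
    sample = sample_scenarios(instance40, 10, seed=5)
    import dataclasses

    gyn_free = MasterSurgerySchedule(
        blocks=tuple(b for b in instance40.mss.blocks if b.specialty != "GYN")
    )
    with pytest.raises(Exception):
        inst2 = dataclasses.replace(instance40, mss=gyn_free)
        solve_advance(inst2, "GYN", sample)
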