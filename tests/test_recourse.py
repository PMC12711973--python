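"""Recourse kernel: realized timelines, policies, and oracle equivalence."""

import numpy as np
import pytest

from orsched.allocation import second_stage_cost
from orsched.recourse import (
    BlockScenarioData,
    BlockSchedule,
    RecourseError,
    batch_costs,
    emergency_wait,
    expected_cost,
    simulate_block,
)
from orsched.scenarios import ScenarioSample, sample_scenarios
from tests.conftest import (
    back_to_back,
    degenerate_scenario,
    make_block,
    make_patient,
    manual_scenario,
    random_schedule,
    single_specialty_instance,
)

C_IDLE = 1.0 / 9.0
C_OVER = 1.0 / 6.0


class TestScheduleValidation:
    def test_first_start_must_be_zero(self):
        b = make_block()
        p = make_patient(0)
        with pytest.raises(RecourseError, match="first scheduled start"):
            BlockSchedule(block=b, patients=(p,), start_times=(5.0,))

    def test_overlap_rejected(self):
        b = make_block()
        ps = (make_patient(0, mu=100), make_patient(1, mu=100))
        with pytest.raises(RecourseError, match="overlaps"):
            BlockSchedule(block=b, patients=ps, start_times=(0.0, 90.0))

    def test_completion_within_block(self):
        b = make_block(length=90)
        p = make_patient(0, mu=100)
        with pytest.raises(RecourseError, match="exceeds block length"):
            BlockSchedule(block=b, patients=(p,), start_times=(0.0,))


class TestDeterministicLimits:
    def test_back_to_back_everything_as_planned(self):
        """rho == mu, all present, no emergency: only idle cost remains."""
        b = make_block()
        ps = [make_patient(i, mu=100 + 10 * i) for i in range(3)]
        sched = back_to_back(b, ps)
        out = simulate_block(sched, degenerate_scenario(ps, [b]), C_IDLE, C_OVER)
        assert out.waiting == (0.0, 0.0, 0.0)
        assert out.overtime == 0.0
        total_mu = sum(p.mean_duration for p in ps)
        assert out.idle == pytest.approx(b.length - total_mu)
        assert out.cost == pytest.approx(C_IDLE * (b.length - total_mu))
        assert out.executed == (1, 1, 1)

    def test_cancellation_of_delayed_patient(self):
        """A long first surgery pushes the second past L + H: cancelled."""
        b = make_block()  # L = 480, H = 60
        ps = [make_patient(0, mu=200), make_patient(1, mu=200, c_sched=40.0)]
        sched = back_to_back(b, ps)
        sc = manual_scenario(ps, b, rot={0: 400.0, 1: 200.0})
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        # q2 = 400, 400 + 200 = 600 > 540
        assert out.executed == (1, 0)
        assert out.last_completion == 400.0
        assert out.overtime == 0.0
        assert out.idle == pytest.approx(480 - 400)
        assert out.canc_cost == ps[1].c_canc
        assert out.waiting == (0.0, 0.0)

    def test_overtime_when_it_fits(self):
        b = make_block()
        ps = [make_patient(0, mu=200), make_patient(1, mu=200)]
        sched = back_to_back(b, ps)
        sc = manual_scenario(ps, b, rot={0: 330.0, 1: 190.0})
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        # q2 = 330, 330 + 200 = 530 <= 540: executed into overtime
        assert out.executed == (1, 1)
        assert out.last_completion == pytest.approx(520.0)
        assert out.overtime == pytest.approx(40.0)
        assert out.waiting[1] == pytest.approx(130.0)

    def test_no_show_collapses_and_frees_time(self):
        b = make_block()
        ps = [make_patient(0, mu=200), make_patient(1, mu=200)]
        sched = back_to_back(b, ps)
        sc = manual_scenario(ps, b, rot={0: 250.0, 1: 150.0}, presence={0: 0})
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        assert out.executed == (1, 1)  # no-shows keep y = 1, cost-free
        assert out.canc_cost == 0.0
        assert out.actual_start[1] == 200.0  # starts on schedule
        assert out.last_completion == pytest.approx(350.0)
        assert out.idle == pytest.approx(480 - 150.0)


class TestEmergencyInsertion:
    def _fixture(self):
        b = make_block()
        ps = [make_patient(0, mu=100), make_patient(1, mu=100)]
        sched = BlockSchedule(
            block=b, patients=tuple(ps), start_times=(0.0, 200.0)
        )
        return b, ps, sched

    def test_idle_room_emergency_starts_at_arrival(self):
        b, ps, sched = self._fixture()
        sc = manual_scenario(ps, b, rot={0: 100.0, 1: 100.0}, delta=50.0, tau=120.0)
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        assert out.emergency_after == (1, 0)
        assert out.em_start == 120.0
        assert out.pre_em_idle == (20.0, 0.0)
        assert emergency_wait(out, sc, b) == 0.0
        assert out.actual_start[1] == 200.0  # emergency ends at 170 < 200
        assert out.waiting == (0.0, 0.0)

    def test_busy_room_emergency_waits_for_completion(self):
        b, ps, sched = self._fixture()
        sc = manual_scenario(ps, b, rot={0: 100.0, 1: 100.0}, delta=150.0, tau=50.0)
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        assert out.emergency_after == (1, 0)
        assert out.em_start == 100.0
        assert out.pre_em_idle == (0.0, 0.0)
        assert emergency_wait(out, sc, b) == 50.0
        assert out.actual_start[1] == 250.0  # pushed by the emergency
        assert out.waiting[1] == pytest.approx(50.0)

    def test_emergency_after_last_elective(self):
        b, ps, sched = self._fixture()
        sc = manual_scenario(ps, b, rot={0: 100.0, 1: 100.0}, delta=60.0, tau=400.0)
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        assert out.emergency_after == (0, 1)
        assert out.em_start == 400.0
        assert out.last_completion == pytest.approx(460.0)

    def test_no_emergency_raises_on_wait_query(self):
        b, ps, sched = self._fixture()
        sc = manual_scenario(ps, b, rot={0: 100.0, 1: 100.0})
        out = simulate_block(sched, sc, C_IDLE, C_OVER)
        with pytest.raises(RecourseError, match="no emergency"):
            emergency_wait(out, sc, b)
        assert out.emergency_after == (0, 0)  # attachment degenerates to a no-op


class TestInvariants:
    def test_conservation_and_bounds_randomized(self, rng):
        """max(L, C) == executed work + delta + idle, on random cases."""
        inst = single_specialty_instance(4, [make_block()], seed=21)
        block = inst.mss.blocks[0]
        sample = sample_scenarios(inst, 40, seed=3)
        for _ in range(25):
            k = int(rng.integers(1, 5))
            pats = list(rng.choice(inst.waiting_list, size=k, replace=False))
            if sum(p.mean_duration for p in pats) > block.length:
                continue
            sched = random_schedule(block, pats, rng)
            for sc in sample.scenarios[:10]:
                out = simulate_block(sched, sc, C_IDLE, C_OVER)
                work = sum(
                    sc.rot[p.id]
                    for i, p in enumerate(sched.patients)
                    if out.present[i] and out.executed[i]
                )
                lhs = max(block.length, out.last_completion)
                assert lhs == pytest.approx(
                    work + sc.em_duration[block.key] + out.idle, abs=1e-9
                )
                assert all(w >= 0 for w in out.waiting)
                assert out.overtime == pytest.approx(
                    max(0.0, out.last_completion - block.length)
                )

    def test_longer_surgery_never_shortens_the_day(self, rng):
        b = make_block()
        ps = [make_patient(i, mu=120) for i in range(3)]
        sched = back_to_back(b, ps)
        base = {0: 150.0, 1: 100.0, 2: 130.0}
        out0 = simulate_block(
            sched, manual_scenario(ps, b, rot=base), C_IDLE, C_OVER
        )
        for bump in (10.0, 50.0, 200.0):
            rot = dict(base)
            rot[1] += bump
            out1 = simulate_block(
                sched, manual_scenario(ps, b, rot=rot), C_IDLE, C_OVER
            )
            assert out1.last_completion >= out0.last_completion - 1e-12


class TestExpectedCost:
    def test_identical_scenarios(self):
        b = make_block()
        ps = [make_patient(0, mu=100)]
        sched = back_to_back(b, ps)
        sc = manual_scenario(ps, b, rot={0: 120.0})
        sample = ScenarioSample(scenarios=(sc,) * 5, seed=0)
        single = simulate_block(sched, sc, C_IDLE, C_OVER).cost
        assert expected_cost(sched, sample, C_IDLE, C_OVER) == pytest.approx(single)

    def test_two_scenario_hand_average(self):
        b = make_block()
        ps = [make_patient(0, mu=100)]
        sched = back_to_back(b, ps)
        s1 = manual_scenario(ps, b, rot={0: 90.0})
        s2 = manual_scenario(ps, b, rot={0: 130.0})
        c1 = simulate_block(sched, s1, C_IDLE, C_OVER).cost
        c2 = simulate_block(sched, s2, C_IDLE, C_OVER).cost
        sample = ScenarioSample(scenarios=(s1, s2), seed=0)
        assert expected_cost(sched, sample, C_IDLE, C_OVER) == pytest.approx(
            (c1 + c2) / 2
        )

    def test_empty_sample_rejected(self):
        b = make_block()
        sched = back_to_back(b, [make_patient(0)])
        with pytest.raises(RecourseError):
            expected_cost(sched, ScenarioSample(scenarios=(), seed=0), C_IDLE, C_OVER)


def test_batch_costs_match_scalar_kernel(rng):
    """The vectorized fitness kernel is bit-compatible with simulate_block."""
    inst = single_specialty_instance(5, [make_block()], seed=23)
    block = inst.mss.blocks[0]
    sample = sample_scenarios(inst, 60, seed=8)
    for _ in range(10):
        k = int(rng.integers(1, 6))
        pats = list(rng.choice(inst.waiting_list, size=k, replace=False))
        if sum(p.mean_duration for p in pats) > block.length:
            continue
        sched = random_schedule(block, pats, rng)
        data = BlockScenarioData.from_sample(
            block, sched.patients, sample, C_IDLE, C_OVER
        )
        vec = batch_costs(
            data, np.arange(len(sched.patients)), np.asarray(sched.start_times)
        )
        scalar = [
            simulate_block(sched, sc, C_IDLE, C_OVER).cost for sc in sample
        ]
        np.testing.assert_allclose(vec, scalar, rtol=0, atol=1e-12)


def test_second_stage_milp_equivalence_sampled(rng):
    """Simulation cost == second-stage MILP optimum on random small cases."""
    inst = single_specialty_instance(6, [make_block()], seed=29)
    block = inst.mss.blocks[0]
    sample = sample_scenarios(inst, 25, seed=13)
    checked = 0
    while checked < 40:
        k = int(rng.integers(1, 5))
        pats = list(rng.choice(inst.waiting_list, size=k, replace=False))
        if sum(p.mean_duration for p in pats) > block.length:
            continue
        sched = random_schedule(block, pats, rng)
        sc = sample.scenarios[int(rng.integers(len(sample)))]
        sim = simulate_block(sched, sc, C_IDLE, C_OVER).cost
        opt = second_stage_cost(sched, sc, C_IDLE, C_OVER)
        assert sim == pytest.approx(opt, abs=1e-6)
        checked += 1
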