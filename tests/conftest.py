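"""Shared fixtures: small instances, hand-built blocks and degenerate samples."""

from __future__ import annotations

import numpy as np
import pytest

from orsched.instances import (
    InstanceConfig,
    MasterSurgerySchedule,
    ORBlock,
    Patient,
    ProblemInstance,
    generate_instance,
    generate_waiting_list,
)
from orsched.scenarios import Scenario, ScenarioSample


def make_patient(
    pid: int,
    mu: float = 100.0,
    sd: float = 20.0,
    specialty: str = "ORTH",
    patient_type: str = "outpatient",
    c_sched: float = 50.0,
    c_wait: float = 1.0 / 60.0,
    no_show_rate: float = 0.0,
) -> Patient:
    mult = 4.0 if patient_type == "inpatient" else 2.0
    return Patient(
        id=pid,
        specialty=specialty,
        group_index=0,
        patient_type=patient_type,
        mean_duration=mu,
        sd_duration=sd,
        no_show_rate=no_show_rate,
        c_sched=c_sched,
        c_canc=mult * c_sched,
        c_wait=c_wait,
    )


def make_block(
    or_id: int = 1, day: str = "Mon", specialty: str = "ORTH",
    length: float = 480.0, max_overtime: float = 60.0,
) -> ORBlock:
    return ORBlock(or_id=or_id, day=day, specialty=specialty,
                   length=length, max_overtime=max_overtime)


def degenerate_scenario(patients, blocks, rot=None) -> Scenario:
    """All present, no emergencies, durations equal to the EOT unless given."""
    rot = rot or {}
    return Scenario(
        rot={p.id: rot.get(p.id, p.mean_duration) for p in patients},
        presence={p.id: 1 for p in patients},
        em_duration={b.key: 0.0 for b in blocks},
        em_arrival={b.key: 0.0 for b in blocks},
    )


def manual_scenario(patients, block, rot, presence=None, delta=0.0, tau=0.0) -> Scenario:
    presence = presence or {}
    return Scenario(
        rot={p.id: rot[p.id] for p in patients},
        presence={p.id: presence.get(p.id, 1) for p in patients},
        em_duration={block.key: delta},
        em_arrival={block.key: tau},
    )


def single_specialty_instance(
    n_patients: int,
    blocks: list[ORBlock],
    seed: int = 0,
    specialty: str | None = None,
    config: InstanceConfig | None = None,
) -> ProblemInstance:
    """Instance whose waiting list is the first n generated patients of the
    blocks' specialty (re-numbered 0..n-1)."""
    specialty = specialty or blocks[0].specialty
    config = config or InstanceConfig()
    pool = generate_waiting_list(6 * n_patients + 60, config=config, seed=seed)
    chosen = [p for p in pool if p.specialty == specialty][:n_patients]
    assert len(chosen) == n_patients
    import dataclasses

    chosen = [dataclasses.replace(p, id=k) for k, p in enumerate(chosen)]
    return ProblemInstance(
        waiting_list=tuple(chosen),
        mss=MasterSurgerySchedule(blocks=tuple(blocks)),
        config=config,
        seed=seed,
    )


@pytest.fixture(scope="session")
def instance40() -> ProblemInstance:
    return generate_instance(40, seed=11)


@pytest.fixture(scope="session")
def big_waiting_list():
    return generate_waiting_list(100_000, seed=17)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def back_to_back(block, patients):
    """Back-to-back schedule in the given order."""
    from orsched.recourse import BlockSchedule

    t, clock = [], 0.0
    for p in patients:
        t.append(clock)
        clock += p.mean_duration
    return BlockSchedule(block=block, patients=tuple(patients), start_times=tuple(t))


def random_schedule(block, patients, rng):
    """Random order and random feasible slack distribution."""
    from orsched.recourse import BlockSchedule

    order = list(rng.permutation(len(patients)))
    seq = [patients[i] for i in order]
    G = block.length - sum(p.mean_duration for p in seq)
    assert G >= 0
    slack = rng.dirichlet(np.ones(len(seq) + 1)) * G
    t, clock = [], 0.0
    for i, p in enumerate(seq):
        t.append(clock)
        clock += p.mean_duration + slack[i]
    return BlockSchedule(block=block, patients=tuple(seq), start_times=tuple(t))
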