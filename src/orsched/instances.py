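"""Problem instances for elective surgery scheduling under uncertainty.

The domain data model covers the waiting list (elective inpatients and
outpatients), the master surgery schedule (MSS) that assigns operating-room
blocks to specialties over a one-week horizon, and the global stochastic and
cost parameters (emergency arrivals, idle/overtime unit costs).  A built-in
generator reproduces a realistic instance family for a five-specialty
operating theater: surgery durations follow per-specialty lognormal mixtures
whose components ("procedure groups") come in two variability classes, and
the inpatient/outpatient label, no-show rate and cost attributes are drawn
conditionally on that class.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SPECIALTIES = ("CARDIO", "GASTRO", "GYN", "ORTH", "URO")

#: empirical share of elective cases per specialty
SPECIALTY_WEIGHTS = {
    "CARDIO": 0.1432,
    "GASTRO": 0.1876,
    "GYN": 0.3043,
    "ORTH": 0.1590,
    "URO": 0.2059,
}

#: coefficient-of-variation threshold separating the two design CVs
#: (0.151 and 0.202); the midpoint classifies every mixture component
CV_SPLIT = 0.175

DAYS = ("Mon", "Tue", "Wed", "Thu", "Fri")


class InstanceError(ValueError):
    """Raised for invalid instance data or generator arguments."""


@dataclass(frozen=True)
class ProcedureGroup:
    """One lognormal mixture component of a specialty's duration distribution."""

    specialty: str
    mean_duration: float  # EOT mu, minutes
    sd_duration: float  # sigma, minutes
    frequency: float  # probability within the specialty
    index: int = 0

    def __post_init__(self) -> None:
        if self.specialty not in SPECIALTIES:
            raise InstanceError(f"unknown specialty {self.specialty!r}")
        if self.mean_duration <= 0 or self.sd_duration <= 0:
            raise InstanceError("procedure group durations must be positive")
        if not 0 < self.frequency <= 1:
            raise InstanceError("frequency must lie in (0, 1]")

    @property
    def cv(self) -> float:
        return self.sd_duration / self.mean_duration

    @property
    def cv_class(self) -> str:
        """'LCV' (low variability) or 'HCV' (high variability)."""
        return "LCV" if self.cv < CV_SPLIT else "HCV"


# Per-specialty mixture parameters: (frequencies, means, SDs), minutes.
_GROUP_TABLE = {
    "CARDIO": (
        (0.047, 0.204, 0.172, 0.07, 0.272, 0.083, 0.151),
        (32.3, 53.4, 67.2, 85.9, 107.9, 136.3, 162.9),
        (4.9, 10.8, 13.6, 17.4, 21.8, 20.6, 24.6),
    ),
    "GASTRO": (
        (0.016, 0.089, 0.224, 0.213, 0.243, 0.182, 0.033),
        (20.0, 41.6, 72.6, 108.7, 159.7, 234.0, 330.4),
        (4.0, 8.4, 14.7, 16.4, 24.1, 35.3, 49.8),
    ),
    "GYN": (
        (0.206, 0.15, 0.271, 0.328, 0.045),
        (24.6, 43.8, 68.2, 124.2, 216.4),
        (5.0, 6.6, 10.3, 25.1, 32.6),
    ),
    "ORTH": (
        (0.04, 0.126, 0.239, 0.535, 0.06),
        (32.9, 63.9, 108.3, 174.3, 243.6),
        (6.7, 9.6, 21.9, 26.3, 49.2),
    ),
    "URO": (
        (0.158, 0.451, 0.36, 0.031),
        (32.1, 58.1, 94.7, 208.8),
        (6.5, 11.7, 19.1, 31.5),
    ),
}


def default_procedure_groups() -> list[ProcedureGroup]:
    """The 28 built-in procedure groups (7 + 7 + 5 + 5 + 4 per specialty)."""
    groups: list[ProcedureGroup] = []
    for spec in SPECIALTIES:
        f, mu, sd = _GROUP_TABLE[spec]
        # printed frequencies can carry rounding slack (CARDIO sums to
        # 0.999); renormalize so each specialty is a proper distribution
        total = sum(f)
        f = tuple(fi / total for fi in f)
        for idx, (fi, mi, si) in enumerate(zip(f, mu, sd)):
            groups.append(
                ProcedureGroup(
                    specialty=spec,
                    mean_duration=mi,
                    sd_duration=si,
                    frequency=fi,
                    index=idx,
                )
            )
    return groups


@dataclass(frozen=True)
class Patient:
    """One elective patient on the waiting list.

    Costs are in abstract cost units; `c_wait` is per minute of direct
    waiting (difference between actual and scheduled start).
    """

    id: int
    specialty: str
    group_index: int
    patient_type: str  # "inpatient" | "outpatient"
    mean_duration: float  # EOT mu_i, minutes
    sd_duration: float  # sigma_i, minutes
    no_show_rate: float  # r_i
    c_sched: float
    c_canc: float
    c_wait: float

    def __post_init__(self) -> None:
        if self.patient_type not in ("inpatient", "outpatient"):
            raise InstanceError(f"bad patient_type {self.patient_type!r}")
        if not 0 <= self.no_show_rate < 1:
            raise InstanceError("no-show rate must lie in [0, 1)")
        if self.mean_duration <= 0 or self.sd_duration <= 0:
            raise InstanceError("patient durations must be positive")


@dataclass(frozen=True)
class ORBlock:
    """One operating room on one day, assigned to a single specialty."""

    or_id: int
    day: str
    specialty: str
    length: float = 480.0  # L_jk, minutes
    max_overtime: float = 60.0  # H, minutes

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InstanceError("block length must be positive")
        if self.max_overtime < 0:
            raise InstanceError("max overtime must be nonnegative")

    @property
    def key(self) -> tuple[int, str]:
        return (self.or_id, self.day)


@dataclass(frozen=True)
class MasterSurgerySchedule:
    """Tactical assignment of OR blocks to specialties over the horizon."""

    blocks: tuple[ORBlock, ...]

    def __post_init__(self) -> None:
        keys = [b.key for b in self.blocks]
        if len(set(keys)) != len(keys):
            raise InstanceError("duplicate (or_id, day) pair in MSS")

    @property
    def or_count(self) -> int:
        return len({b.or_id for b in self.blocks})

    @property
    def days(self) -> tuple[str, ...]:
        return tuple(d for d in DAYS if any(b.day == d for b in self.blocks))

    def blocks_for(self, specialty: str) -> list[ORBlock]:
        return [b for b in self.blocks if b.specialty == specialty]

    def specialties(self) -> set[str]:
        return {b.specialty for b in self.blocks}


# Default weekly MSS: 9 ORs, 26 blocks over Mon-Fri.  The specialty multiset
# per OR is fixed; day placement uses the earliest weekdays, except OR 9
# which hosts no block on Monday.
_DEFAULT_MSS_ROWS: dict[int, list[tuple[str, str]]] = {
    1: [("Mon", "GASTRO"), ("Tue", "GYN"), ("Wed", "GYN")],
    2: [("Mon", "GASTRO"), ("Tue", "GYN"), ("Wed", "GYN"), ("Thu", "GYN"), ("Fri", "GASTRO")],
    3: [("Mon", "CARDIO"), ("Tue", "CARDIO"), ("Wed", "CARDIO")],
    4: [("Mon", "URO"), ("Tue", "URO"), ("Wed", "URO")],
    5: [("Mon", "ORTH"), ("Tue", "ORTH"), ("Wed", "URO")],
    6: [("Mon", "ORTH"), ("Tue", "ORTH")],
    7: [("Mon", "ORTH"), ("Tue", "ORTH"), ("Wed", "ORTH")],
    8: [("Mon", "GASTRO"), ("Tue", "GASTRO")],
    9: [("Tue", "GYN"), ("Wed", "GASTRO")],
}


def default_mss(length: float = 480.0, max_overtime: float = 60.0) -> MasterSurgerySchedule:
    """The shipped default MSS: 9 ORs, 26 blocks, 480-min blocks, 60-min cap."""
    blocks = [
        ORBlock(or_id=j, day=day, specialty=spec, length=length, max_overtime=max_overtime)
        for j, row in _DEFAULT_MSS_ROWS.items()
        for day, spec in row
    ]
    return MasterSurgerySchedule(blocks=tuple(blocks))


@dataclass(frozen=True)
class InstanceConfig:
    """Global stochastic and cost parameters of an instance."""

    p_em: float = 0.2  # probability of an emergency insertion per block
    mu_em: float = 93.0  # emergency duration mean, minutes
    sigma_em: float = 60.0  # emergency duration SD, minutes
    em_truncation: float = 240.0  # emergency duration cap, minutes
    c_idle: float = 1.0 / 9.0  # c^g, cost per idle minute
    c_over: float = 1.0 / 6.0  # c^h, cost per overtime minute
    delta_sched: float = 10.0  # scheduling-cost grid step
    inpatient_share_given_lcv: float = 0.3
    inpatient_share_given_hcv: float = 0.7
    no_show_inpatient: float = 0.08
    no_show_outpatient: float = 0.24
    specialty_weights: dict[str, float] = field(
        default_factory=lambda: dict(SPECIALTY_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for name in ("p_em", "inpatient_share_given_lcv", "inpatient_share_given_hcv",
                     "no_show_inpatient", "no_show_outpatient"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InstanceError(f"{name} must lie in [0, 1], got {v}")
        total = sum(self.specialty_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InstanceError(f"specialty weights sum to {total}, expected 1")


@dataclass(frozen=True)
class ProblemInstance:
    """Waiting list + MSS + global parameters; the unit every stage consumes."""

    waiting_list: tuple[Patient, ...]
    mss: MasterSurgerySchedule
    config: InstanceConfig
    seed: int = 0

    def __post_init__(self) -> None:
        available = self.mss.specialties()
        missing = {p.specialty for p in self.waiting_list} - available
        if missing:
            raise InstanceError(
                f"patients of specialties {sorted(missing)} have no OR block in the MSS"
            )

    def patients_of(self, specialty: str) -> list[Patient]:
        return [p for p in self.waiting_list if p.specialty == specialty]

    def patient_by_id(self, pid: int) -> Patient:
        for p in self.waiting_list:
            if p.id == pid:
                return p
        raise KeyError(pid)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream keyed on (seed, *key)."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, *key))))


def generate_waiting_list(
    n: int,
    config: InstanceConfig | None = None,
    seed: int = 0,
    groups: Sequence[ProcedureGroup] | None = None,
) -> list[Patient]:
    """Generate ``n`` elective patients.

    Each patient draws a specialty from the empirical case-mix weights, a
    procedure group from the specialty's mixture frequencies, an
    inpatient/outpatient label conditional on the group's variability class,
    and costs: ``c_sched`` uniform on {10, 20, ..., 100}; cancellation cost 4x
    (inpatients) or 2x (outpatients) the scheduling cost; waiting cost per
    minute uniform on [1/360, 1/36] for inpatients and [1/180, 1/18] for
    outpatients.  Deterministic under a fixed ``(n, config, seed)``.
    """
    if n < 1:
        raise InstanceError(f"n must be >= 1, got {n}")
    config = config or InstanceConfig()
    groups = list(groups) if groups is not None else default_procedure_groups()

    specs = [s for s in SPECIALTIES if s in config.specialty_weights]
    weights = np.array([config.specialty_weights[s] for s in specs])
    weights = weights / weights.sum()
    by_spec = {s: [g for g in groups if g.specialty == s] for s in specs}

    rng = _rng(seed, 0)
    spec_idx = rng.choice(len(specs), size=n, p=weights)
    patients: list[Patient] = []
    n_steps = 10  # c_sched grid {1..10} * delta
    for i in range(n):
        s = specs[spec_idx[i]]
        gs = by_spec[s]
        freqs = np.array([g.frequency for g in gs])
        g = gs[rng.choice(len(gs), p=freqs / freqs.sum())]
        p_in = (
            config.inpatient_share_given_lcv
            if g.cv_class == "LCV"
            else config.inpatient_share_given_hcv
        )
        inpatient = rng.random() < p_in
        c_sched = config.delta_sched * (1 + rng.integers(n_steps))
        if inpatient:
            c_canc = 4.0 * c_sched
            c_wait = rng.uniform(1.0 / 360.0, 1.0 / 36.0)
            r = config.no_show_inpatient
        else:
            c_canc = 2.0 * c_sched
            c_wait = rng.uniform(1.0 / 180.0, 1.0 / 18.0)
            r = config.no_show_outpatient
        patients.append(
            Patient(
                id=i,
                specialty=s,
                group_index=g.index,
                patient_type="inpatient" if inpatient else "outpatient",
                mean_duration=g.mean_duration,
                sd_duration=g.sd_duration,
                no_show_rate=r,
                c_sched=float(c_sched),
                c_canc=float(c_canc),
                c_wait=float(c_wait),
            )
        )
    return patients


def generate_instance(
    n: int,
    seed: int = 0,
    config: InstanceConfig | None = None,
    mss: MasterSurgerySchedule | None = None,
) -> ProblemInstance:
    """Convenience wrapper: default MSS + generated waiting list."""
    config = config or InstanceConfig()
    mss = mss or default_mss()
    patients = generate_waiting_list(n, config=config, seed=seed)
    return ProblemInstance(
        waiting_list=tuple(patients), mss=mss, config=config, seed=seed
    )


# ---------------------------------------------------------------------------
# serialization

_PATIENT_FIELDS = [f.name for f in dataclasses.fields(Patient)]


def write_instance(instance: ProblemInstance, path: str | Path) -> None:
    """Serialize an instance to JSON (keys: config, mss, patients, seed)."""
    doc = {
        "config": dataclasses.asdict(instance.config),
        "mss": [dataclasses.asdict(b) for b in instance.mss.blocks],
        "patients": [dataclasses.asdict(p) for p in instance.waiting_list],
        "seed": instance.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_instance(path: str | Path) -> ProblemInstance:
    """Read an instance written by :func:`write_instance`.

    Raises :class:`InstanceError` naming the offending field on malformed
    input.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InstanceError(f"not valid JSON: {exc}") from exc
    for key in ("config", "mss", "patients"):
        if key not in doc:
            raise InstanceError(f"missing top-level key {key!r}")
    try:
        config = InstanceConfig(**doc["config"])
    except TypeError as exc:
        raise InstanceError(f"bad config section: {exc}") from exc
    blocks = []
    for row in doc["mss"]:
        try:
            blocks.append(ORBlock(**row))
        except TypeError as exc:
            raise InstanceError(f"bad MSS block {row!r}: {exc}") from exc
    patients = []
    for row in doc["patients"]:
        missing = [f for f in _PATIENT_FIELDS if f not in row]
        if missing:
            raise InstanceError(
                f"patient record missing field(s) {missing} (id={row.get('id')})"
            )
        patients.append(Patient(**row))
    return ProblemInstance(
        waiting_list=tuple(patients),
        mss=MasterSurgerySchedule(blocks=tuple(blocks)),
        config=config,
        seed=int(doc.get("seed", 0)),
    )


def patients_to_csv(instance: ProblemInstance, path: str | Path) -> None:
    """Export the waiting list as CSV, one row per patient."""
    df = pd.DataFrame([dataclasses.asdict(p) for p in instance.waiting_list])
    df.to_csv(path, index=False)


def lcv_probability(groups: Sequence[ProcedureGroup] | None = None,
                    config: InstanceConfig | None = None) -> float:
    """P(generated patient's group is low-CV) under the generator's mixtures."""
    groups = list(groups) if groups is not None else default_procedure_groups()
    config = config or InstanceConfig()
    p = 0.0
    for s, w in config.specialty_weights.items():
        for g in groups:
            if g.specialty == s and g.cv_class == "LCV":
                p += w * g.frequency
    return p
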