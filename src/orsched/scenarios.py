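"""Scenario sampling for the random vector (rho, delta, tau, theta).

One scenario is a joint realization of every stochastic element of the
problem: elective real operating times rho_i (lognormal, moment-matched to
each patient's EOT mean/SD), patient presence theta_i (Bernoulli(1 - r_i),
0 = no-show), and per-block emergency surgeries: with probability ``p_em`` a
block receives one emergency of lognormal duration delta (truncated by
rejection at ``em_truncation``) arriving uniformly over the block's opening
hours.  Scenario sets are generated once per run and shared by every solver
stage so that configurations are compared on identical noise.

Sub-streams are keyed on (seed, kind, patient/block index): adding a patient
or block never perturbs the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instances import ORBlock, ProblemInstance, _rng


class ScenarioError(ValueError):
    pass


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (m, s) of a lognormal with arithmetic mean/SD (moment match).

    s^2 = ln(1 + (sd/mean)^2),  m = ln(mean) - s^2 / 2.
    """
    if mean <= 0 or sd <= 0:
        raise ScenarioError("lognormal moments must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))


@dataclass(frozen=True)
class Scenario:
    """One joint realization, indexed by patient id and block key."""

    rot: dict[int, float]  # rho_i, minutes
    presence: dict[int, int]  # theta_i in {0, 1}
    em_duration: dict[tuple[int, str], float]  # delta_jk, 0 = no emergency
    em_arrival: dict[tuple[int, str], float]  # tau_jk, minutes from block start


@dataclass(frozen=True)
class ScenarioSample:
    scenarios: tuple[Scenario, ...]
    seed: int

    @property
    def size(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)


def _truncated_lognormal(
    rng: np.random.Generator, m: float, s: float, n: int, cap: float
) -> np.ndarray:
    """Rejection sampling: resample any draw above ``cap`` (keeps the
    lognormal shape below the cap, no atom at the boundary)."""
    out = rng.lognormal(m, s, size=n)
    bad = out > cap
    while bad.any():
        out[bad] = rng.lognormal(m, s, size=int(bad.sum()))
        bad = out > cap
    return out


def sample_scenarios(
    instance: ProblemInstance, n: int, seed: int = 0
) -> ScenarioSample:
    """Draw ``n`` i.i.d. scenarios for every patient and block of ``instance``."""
    if n < 1:
        raise ScenarioError(f"sample size must be >= 1, got {n}")
    cfg = instance.config

    rots: dict[int, np.ndarray] = {}
    thetas: dict[int, np.ndarray] = {}
    for p in instance.waiting_list:
        m, s = lognormal_params(p.mean_duration, p.sd_duration)
        r = _rng(seed, 1, p.id)
        rots[p.id] = r.lognormal(m, s, size=n)
        thetas[p.id] = (r.random(n) < 1.0 - p.no_show_rate).astype(np.int64)

    m_em, s_em = lognormal_params(cfg.mu_em, cfg.sigma_em)
    durs: dict[tuple[int, str], np.ndarray] = {}
    arrs: dict[tuple[int, str], np.ndarray] = {}
    for bi, block in enumerate(instance.mss.blocks):
        r = _rng(seed, 2, bi)
        occurs = r.random(n) < cfg.p_em
        d = np.zeros(n)
        a = np.zeros(n)
        k = int(occurs.sum())
        if k:
            d[occurs] = _truncated_lognormal(r, m_em, s_em, k, cfg.em_truncation)
            a[occurs] = r.uniform(0.0, block.length, size=k)
        durs[block.key] = d
        arrs[block.key] = a

    scenarios = tuple(
        Scenario(
            rot={pid: float(v[w]) for pid, v in rots.items()},
            presence={pid: int(v[w]) for pid, v in thetas.items()},
            em_duration={key: float(v[w]) for key, v in durs.items()},
            em_arrival={key: float(v[w]) for key, v in arrs.items()},
        )
        for w in range(n)
    )
    return ScenarioSample(scenarios=scenarios, seed=seed)


def partition_folds(sample: ScenarioSample, n_folds: int) -> list[ScenarioSample]:
    """Split a sample into ``n_folds`` disjoint, covering folds.

    Folds have size ``|S| // n_folds``; when ``n_folds`` does not divide the
    sample size the last fold absorbs the remainder.
    """
    if n_folds < 1 or n_folds > sample.size:
        raise ScenarioError(
            f"fold count must lie in [1, {sample.size}], got {n_folds}"
        )
    base = sample.size // n_folds
    folds = []
    for f in range(n_folds):
        lo = f * base
        hi = sample.size if f == n_folds - 1 else lo + base
        folds.append(
            ScenarioSample(scenarios=sample.scenarios[lo:hi], seed=sample.seed)
        )
    return folds


def sample_emergency_durations(
    config, n: int, seed: int = 0, truncate: bool = True
) -> np.ndarray:
    """Draw ``n`` emergency surgery durations (minutes).

    With ``truncate=False`` returns raw lognormal draws with arithmetic mean
    ``mu_em`` and SD ``sigma_em``; otherwise rejection-truncated at
    ``em_truncation``.
    """
    if n < 1:
        raise ScenarioError(f"n must be >= 1, got {n}")
    m, s = lognormal_params(config.mu_em, config.sigma_em)
    rng = _rng(seed, 3)
    if not truncate:
        return rng.lognormal(m, s, size=n)
    return _truncated_lognormal(rng, m, s, n, config.em_truncation)


def sample_poisson_emergencies(
    instance: ProblemInstance, block: ORBlock, n: int, seed: int = 0
) -> list[list[tuple[float, float]]]:
    """Per-scenario emergency lists for one block under Poisson arrivals.

    Relaxes the at-most-one-emergency assumption: the number of emergencies
    per block scenario is Poisson with the same mean ``p_em`` as the Bernoulli
    model; arrivals are i.i.d. uniform on [0, L] and returned sorted, each
    paired with a truncated-lognormal duration.
    """
    if n < 1:
        raise ScenarioError(f"n must be >= 1, got {n}")
    cfg = instance.config
    m_em, s_em = lognormal_params(cfg.mu_em, cfg.sigma_em)
    bi = [b.key for b in instance.mss.blocks].index(block.key)
    r = _rng(seed, 4, bi)
    counts = r.poisson(cfg.p_em, size=n)
    out: list[list[tuple[float, float]]] = []
    for c in counts:
        if c == 0:
            out.append([])
            continue
        arr = np.sort(r.uniform(0.0, block.length, size=int(c)))
        dur = _truncated_lognormal(r, m_em, s_em, int(c), cfg.em_truncation)
        out.append([(float(a), float(d)) for a, d in zip(arr, dur)])
    return out
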