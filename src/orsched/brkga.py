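"""Biased random-key genetic algorithm for sequencing + timing of one block.

A candidate schedule is a chromosome of 2|I| unit-interval genes: the first
half orders the surgeries (ascending gene value, ties broken by patient id),
the second half distributes the block's planned idle time
``G = L - sum mu_i`` as slacks.  The gene at *position* p of the second half
(after reordering) buys a slack of ``gamma'_p / sum(gamma') * G`` after the
p-th surgery; the last position's share is the end-of-block slack.  Every
chromosome therefore decodes to a feasible schedule (first start 0, no
planned overlap, planned completion within L), so the whole population
explores the search space.

Evolution is the classic elitist scheme: elites copied verbatim, a fraction
of fresh random mutants, and the rest bred by biased crossover where each
gene comes from the elite parent with probability p_bias.  Fitness is the
sample-average recourse cost, evaluated with the vectorized simulation
kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from time import perf_counter

import numpy as np

from .allocation import AllocationSolution
from .instances import ORBlock, Patient, _rng
from .recourse import BlockScenarioData, BlockSchedule, batch_costs
from .scenarios import ScenarioSample


class BrkgaError(ValueError):
    pass


@dataclass(frozen=True)
class BRKGAConfig:
    population: int = 50
    elite_fraction: float = 0.25
    mutant_fraction: float = 0.2
    inherit_prob: float = 0.5  # probability a gene comes from the elite parent
    max_generations: int = 200
    time_limit: float | None = None  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elite_fraction + self.mutant_fraction >= 1:
            raise BrkgaError("elite + mutant fractions must be < 1")
        if not 0 < self.inherit_prob < 1:
            raise BrkgaError("inherit_prob must lie in (0, 1)")
        if self.population < 3:
            raise BrkgaError("population must allow elites, mutants and offspring")

    @property
    def n_elite(self) -> int:
        return max(1, int(self.population * self.elite_fraction))

    @property
    def n_mutant(self) -> int:
        return int(self.population * self.mutant_fraction)


def decode(
    chromosome: np.ndarray,
    patients: list[Patient] | tuple[Patient, ...],
    block: ORBlock,
) -> BlockSchedule:
    """Decode a 2|I|-gene chromosome into a feasible block schedule."""
    patients = tuple(patients)
    n = len(patients)
    genes = np.asarray(chromosome, dtype=float)
    if genes.shape != (2 * n,):
        raise BrkgaError(f"chromosome must have length {2 * n}")
    if ((genes < 0) | (genes > 1)).any():
        raise BrkgaError("genes must lie in [0, 1]")
    total_mu = sum(p.mean_duration for p in patients)
    if total_mu > block.length + 1e-9:
        raise BrkgaError("total EOT exceeds block length")
    seq_genes = genes[:n]
    tim_genes = genes[n:]
    # ascending sequencing genes; stable tie-break by patient id
    order = sorted(range(n), key=lambda i: (seq_genes[i], patients[i].id))
    G = block.length - total_mu
    denom = tim_genes.sum()
    shares = tim_genes / denom if denom > 0 else np.zeros(n)
    t, clock = [], 0.0
    for pos, i in enumerate(order):
        t.append(clock)
        clock += patients[i].mean_duration + shares[pos] * G
    return BlockSchedule(
        block=block,
        patients=tuple(patients[i] for i in order),
        start_times=tuple(t),
    )


@dataclass(frozen=True)
class EvolutionTrace:
    best_fitness: tuple[float, ...]  # best-ever value per generation
    generations: int


def evolve(
    patients: list[Patient] | tuple[Patient, ...],
    block: ORBlock,
    sample: ScenarioSample,
    c_idle: float,
    c_over: float,
    config: BRKGAConfig | None = None,
    return_trace: bool = False,
):
    """Run the BRKGA; returns an :class:`AllocationSolution` (optionally with
    the per-generation best-fitness trace)."""
    config = config or BRKGAConfig()
    patients = tuple(patients)
    n = len(patients)
    if n < 1:
        raise BrkgaError("need at least one patient")
    data = BlockScenarioData.from_sample(block, patients, sample, c_idle, c_over)
    rng = _rng(config.seed, 5)

    def fitness(genome: np.ndarray) -> float:
        sched = decode(genome, patients, block)
        idx = {p.id: k for k, p in enumerate(patients)}
        order = np.array([idx[p.id] for p in sched.patients])
        return float(
            np.mean(batch_costs(data, order, np.asarray(sched.start_times)))
        )

    P = config.population
    pop = rng.random((P, 2 * n))
    fit = np.array([fitness(pop[k]) for k in range(P)])
    best_hist: list[float] = []
    start = perf_counter()
    gen = 0
    for gen in range(1, config.max_generations + 1):
        rank = np.argsort(fit, kind="stable")
        pop, fit = pop[rank], fit[rank]
        best_hist.append(float(fit[0]))
        if config.time_limit is not None and perf_counter() - start > config.time_limit:
            break
        ne, nm = config.n_elite, config.n_mutant
        nxt = np.empty_like(pop)
        nxt[:ne] = pop[:ne]
        nxt[ne : ne + nm] = rng.random((nm, 2 * n))
        for k in range(ne + nm, P):
            elite = pop[rng.integers(ne)]
            other = pop[ne + rng.integers(P - ne)]
            mask = rng.random(2 * n) < config.inherit_prob
            nxt[k] = np.where(mask, elite, other)
        pop = nxt
        fit = np.concatenate(
            [fit[:ne], [fitness(pop[k]) for k in range(ne, P)]]
        )
    rank = np.argsort(fit, kind="stable")
    pop, fit = pop[rank], fit[rank]
    best_hist.append(float(fit[0]))
    schedule = decode(pop[0], patients, block)
    sol = AllocationSolution(
        schedule=schedule,
        expected_cost=float(fit[0]),
        status="feasible",
        objective=float(fit[0]),
    )
    if return_trace:
        return sol, EvolutionTrace(best_fitness=tuple(best_hist), generations=gen)
    return sol
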