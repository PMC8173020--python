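"""Finite-population stochastic simulation of cage dynamics.

Wright-Fisher-style sampling on top of the extreme-underdominance
recursion: each generation the deterministic map gives the expected
construct-homozygote frequency, and the realized next generation is one
binomial draw of the whole (constant-size) population.  Generations are
non-overlapping; there is no individual-based mating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cage_data import CageObservation, Experiment, ExperimentSet
from .systems import step_extreme_ud

__all__ = ["StochasticConfig", "sample_next_generation", "simulate_cage"]


@dataclass(frozen=True)
class StochasticConfig:
    """Population size, horizon, replication and seeding of a simulation.

    ``population_size`` defaults to 50, the census used for the
    stochastic cage predictions; replicate ``r`` draws from its own
    generator seeded with ``seed + r`` so individual replicates are
    reproducible in isolation.
    """

    population_size: int = 50
    generations: int = 10
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def sample_next_generation(
    p_expected: float, n: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw next-generation counts: TT ~ Binomial(n, p_expected)."""
    if not (0.0 <= p_expected <= 1.0):
        raise ValueError(f"expected frequency must be in [0, 1]; got {p_expected}")
    tt = int(rng.binomial(n, p_expected))
    return tt, n - tt


def simulate_cage(
    s: float,
    release: float,
    cfg: StochasticConfig,
    first_experiment_id: int = 0,
) -> ExperimentSet:
    """Simulate replicate cages of the extreme-underdominance system.

    Each replicate starts from ``round(N * release)`` construct
    homozygotes at generation 0; every later generation applies the
    deterministic recursion to the *realized* frequency and takes one
    binomial sample of size ``N``.
    """
    if not (0.0 <= release <= 1.0):
        raise ValueError(f"release frequency must be in [0, 1]; got {release}")
    n = cfg.population_size
    experiments = []
    for r in range(cfg.replicates):
        rng = np.random.default_rng(cfg.seed + r)
        tt = int(round(n * release))
        obs = [CageObservation(first_experiment_id + r, 0, tt, n - tt)]
        for k in range(1, cfg.generations + 1):
            p_next = step_extreme_ud(tt / n, s)
            tt, wt = sample_next_generation(p_next, n, rng)
            obs.append(CageObservation(first_experiment_id + r, k, tt, wt))
        experiments.append(
            Experiment(first_experiment_id + r, release, tuple(obs))
        )
    return ExperimentSet(tuple(experiments))
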