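"""Synthetic cage-experiment datasets with the study's design structure.

Generates count tables with the same statistical structure the inference
assumes: a grid of release frequencies, replicate cages per release,
exact generation-0 release counts, and later generations produced by the
deterministic recursion plus whole-population binomial sampling.  The
defaults mirror the cage-study design: releases of 50/70/80/90%
construct homozygotes, at least three replicates per release, starting
populations of 100 adults, tracked for up to 11 generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cage_data import Experiment, ExperimentSet
from .stochastic import StochasticConfig, simulate_cage

__all__ = ["SyntheticStudyDesign", "generate_cage_counts", "reference_study_design"]

#: Fitted fitness cost of the reference strain, used by the demo design.
REFERENCE_FITNESS_COST = 0.3484


@dataclass(frozen=True)
class SyntheticStudyDesign:
    """Parameters of a synthetic cage study.

    ``population_size`` is both the number of released adults and the
    constant census size of every later generation (Wright-Fisher
    sampling at fixed N).  ``dropout_probability`` optionally truncates
    a cage at a random generation, emulating replicate attrition; it
    defaults to 0 (no attrition).
    """

    fitness_cost: float
    release_frequencies: tuple[float, ...] = (0.5, 0.7, 0.8, 0.9)
    replicates_per_release: int = 3
    generations: int = 11
    population_size: int = 100
    seed: int = 0
    dropout_probability: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fitness_cost < 1.0):
            raise ValueError("fitness_cost must be in [0, 1)")
        if self.replicates_per_release < 1:
            raise ValueError("replicates_per_release must be >= 1")
        if not (0.0 <= self.dropout_probability <= 1.0):
            raise ValueError("dropout_probability must be in [0, 1]")


def generate_cage_counts(design: SyntheticStudyDesign) -> ExperimentSet:
    """Simulate the full study grid: one experiment per release x replicate.

    Experiment ids run sequentially over the grid; each release
    condition uses its own deterministic block of replicate seeds, so
    the whole dataset is reproducible from ``design.seed``.
    """
    experiments: list[Experiment] = []
    next_id = 0
    for c, release in enumerate(design.release_frequencies):
        cfg = StochasticConfig(
            population_size=design.population_size,
            generations=design.generations,
            replicates=design.replicates_per_release,
            seed=design.seed + 10_000 * c,
        )
        batch = simulate_cage(
            design.fitness_cost, release, cfg, first_experiment_id=next_id
        )
        experiments.extend(batch)
        next_id += design.replicates_per_release
    if design.dropout_probability > 0.0:
        rng = np.random.default_rng(design.seed + 999_983)
        truncated = []
        for e in experiments:
            if rng.random() < design.dropout_probability and e.n_generations > 1:
                stop = int(rng.integers(1, e.n_generations)) + 1
                e = Experiment(e.experiment_id, e.release_frequency,
                               e.observations[:stop])
            truncated.append(e)
        experiments = truncated
    return ExperimentSet(tuple(experiments))


def reference_study_design(seed: int = 0) -> SyntheticStudyDesign:
    """The default study design at the fitted reference fitness cost.

    Releases {50, 70, 80, 90}%, three replicates each, 11 generations,
    starting populations of 100 adults, s = 34.84%.
    """
    return SyntheticStudyDesign(fitness_cost=REFERENCE_FITNESS_COST, seed=seed)
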