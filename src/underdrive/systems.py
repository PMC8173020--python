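"""Deterministic one-generation dynamics of underdominant gene-drive systems.

Three architectures are modeled, all with discrete non-overlapping
generations, random mating, and an infinite (frequency-based) population:

* **Extreme underdominance** — a single construct allele ``T`` whose
  heterozygotes with the wildtype allele ``t`` are unviable, leaving only
  the two homozygote classes ``TT`` and ``tt``.  Writing ``p`` for the
  ``TT`` frequency and ``s`` for the construct fitness cost, the census
  frequency obeys the recursion

      p' = p^2 (1 - s) / (p^2 (1 - s) + (1 - p)^2)

  with stable fixed points 0 and 1 and an unstable internal equilibrium
  (the release threshold) at ``1 / (2 - s)``.

* **Reciprocal chromosomal translocation** — genotypes ``TT``, ``Tt``,
  ``tt``.  Translocation heterozygotes produce half balanced gametes
  (one quarter ``T``, one quarter ``t``) and half unbalanced gametes;
  any zygote formed from an unbalanced gamete dies.

* **Two-locus engineered underdominance** — two unlinked constructs
  ``A`` and ``B``, each carrying a lethal suppressed by the other, so a
  genotype bearing one construct type without any copy of the other is
  unviable.  Nine genotypes ``{AA,Aa,aa} x {BB,Bb,bb}``; gametes assort
  independently.

Selection convention: the census is taken on offspring after viability
selection, with genotype fitnesses applied once per generation.  For
extreme underdominance this makes the closed-form recursion above exact;
for the comparative systems the fitness cost is additive per construct
copy (``TT``: 1-s, ``Tt``: 1-s/2; two-locus: ``1 - s*c/4`` for ``c``
construct alleles), so the fully homozygous release genotype always
carries cost ``s``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "System",
    "DriveSystemSpec",
    "PopulationState",
    "Fate",
    "Trajectory",
    "genotype_labels",
    "construct_copies",
    "release_state",
    "step_extreme_ud",
    "step_translocation",
    "step_two_locus",
    "step_state",
    "carrier_frequency",
    "iterate",
]

_NORM_TOL = 1e-8


class System(str, enum.Enum):
    """The underdominant architectures supported by the model suite."""

    EXTREME_UD = "extreme_ud"
    TRANSLOCATION = "translocation"
    TWO_LOCUS_UD = "two_locus_ud"


#: Genotype labels, in census order, per system.
_GENOTYPES = {
    System.EXTREME_UD: ("TT", "tt"),
    System.TRANSLOCATION: ("TT", "Tt", "tt"),
    System.TWO_LOCUS_UD: (
        "AABB", "AABb", "AAbb",
        "AaBB", "AaBb", "Aabb",
        "aaBB", "aaBb", "aabb",
    ),
}

#: Number of construct alleles carried by each genotype (same order).
_COPIES = {
    System.EXTREME_UD: (2, 0),
    System.TRANSLOCATION: (2, 1, 0),
    System.TWO_LOCUS_UD: (4, 3, 2, 3, 2, 1, 2, 1, 0),
}


def genotype_labels(system: System) -> tuple[str, ...]:
    return _GENOTYPES[System(system)]


def construct_copies(system: System) -> tuple[int, ...]:
    return _COPIES[System(system)]


@dataclass(frozen=True)
class DriveSystemSpec:
    """An underdominant system together with its fitness cost.

    Parameters
    ----------
    system
        Which architecture is modeled.
    fitness_cost
        Relative fecundity/viability reduction ``s`` of the fully
        homozygous construct genotype versus wildtype, in ``[0, 1)``.
        ``s = 1`` is rejected: the extreme-underdominance recursion
        degenerates (zero denominator at fixation).
    """

    system: System
    fitness_cost: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", System(self.system))
        s = self.fitness_cost
        if not (0.0 <= s < 1.0):
            raise ValueError(f"fitness_cost must be in [0, 1); got {s}")

    @property
    def n_genotypes(self) -> int:
        return len(_GENOTYPES[self.system])


@dataclass(frozen=True)
class PopulationState:
    """Genotype frequencies of one population at a census.

    Frequencies are indexed by :func:`genotype_labels` for the system,
    must be non-negative and sum to one.  The state is the post-selection
    (adult) census; for extreme underdominance the heterozygote class is
    absent by construction.
    """

    system: System
    frequencies: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", System(self.system))
        freqs = np.asarray(self.frequencies, dtype=float)
        labels = _GENOTYPES[self.system]
        if freqs.shape != (len(labels),):
            raise ValueError(
                f"{self.system.value} expects {len(labels)} genotype "
                f"frequencies {labels}; got shape {freqs.shape}"
            )
        if np.any(freqs < -_NORM_TOL) or abs(freqs.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"genotype frequencies must be non-negative and sum to 1; "
                f"got {freqs.tolist()} (sum {freqs.sum():.12g})"
            )
        freqs = np.clip(freqs, 0.0, None)
        freqs = freqs / freqs.sum()
        freqs.flags.writeable = False
        object.__setattr__(self, "frequencies", freqs)

    @property
    def labels(self) -> tuple[str, ...]:
        return _GENOTYPES[self.system]

    def frequency(self, label: str) -> float:
        return float(self.frequencies[self.labels.index(label)])


def release_state(system: System, release: float, generation: int = 0) -> PopulationState:
    """State just after releasing construct homozygotes into wildtype.

    A release at frequency ``f`` replaces the adult pool with ``f``
    fully homozygous construct individuals (``TT`` or ``AABB``) and
    ``1 - f`` wildtype; no fitness cost applies at the release census
    itself (the released adults are already viable).
    """
    system = System(system)
    if not (0.0 <= release <= 1.0):
        raise ValueError(f"release frequency must be in [0, 1]; got {release}")
    freqs = np.zeros(len(_GENOTYPES[system]))
    freqs[0] = release
    freqs[-1] = 1.0 - release
    return PopulationState(system, freqs, generation)


def step_extreme_ud(p: float, s: float) -> float:
    """One generation of the extreme-underdominance recursion.

    ``p`` is the construct-homozygote frequency; heterozygous offspring
    die, ``TT`` offspring survive with relative viability ``1 - s``.
    Accepts scalars or numpy arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must be in [0, 1]")
    if not (0.0 <= s < 1.0):
        raise ValueError(f"fitness cost must be in [0, 1); got {s}")
    num = p * p * (1.0 - s)
    out = num / (num + (1.0 - p) ** 2)
    return float(out) if out.ndim == 0 else out


def _check_state(state: PopulationState, system: System) -> np.ndarray:
    if state.system is not System(system):
        raise ValueError(f"state is for {state.system.value}, expected {System(system).value}")
    return state.frequencies


def step_translocation(state: PopulationState, s: float) -> PopulationState:
    """One generation of the reciprocal-translocation model.

    Balanced gametes: homozygotes transmit their own chromosome type;
    heterozygotes transmit 1/4 ``T``, 1/4 ``t`` and 1/2 unbalanced.
    Zygotes receiving any unbalanced gamete die; surviving zygotes are
    weighted by viabilities ``(1-s, 1-s/2, 1)`` and renormalized.
    """
    x = _check_state(state, System.TRANSLOCATION)
    if not (0.0 <= s < 1.0):
        raise ValueError(f"fitness cost must be in [0, 1); got {s}")
    g_T = x[0] + x[1] / 4.0
    g_t = x[2] + x[1] / 4.0
    zyg = np.array([g_T * g_T, 2.0 * g_T * g_t, g_t * g_t])
    zyg *= np.array([1.0 - s, 1.0 - s / 2.0, 1.0])
    zyg /= zyg.sum()
    return PopulationState(System.TRANSLOCATION, zyg, state.generation + 1)


# Two-locus bookkeeping: gamete order (AB, Ab, aB, ab); per-genotype gamete
# distributions and the gamete-pair -> zygote map are precomputed once.
def _two_locus_tables():
    n_A = np.array([2, 2, 2, 1, 1, 1, 0, 0, 0])
    n_B = np.array([2, 1, 0, 2, 1, 0, 2, 1, 0])
    pA, pB = n_A / 2.0, n_B / 2.0
    gametes = np.stack(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)], axis=1
    )  # (9 genotypes, 4 gamete types)
    carries = [(1, 1), (1, 0), (0, 1), (0, 0)]
    pair_to_zygote = np.zeros((4, 4), dtype=int)
    for i, (a1, b1) in enumerate(carries):
        for j, (a2, b2) in enumerate(carries):
            pair_to_zygote[i, j] = (2 - (a1 + a2)) * 3 + (2 - (b1 + b2))
    viable = np.where((n_A > 0) & (n_B == 0) | ((n_B > 0) & (n_A == 0)), 0.0, 1.0)
    return gametes, pair_to_zygote, viable, n_A + n_B


_TL_GAMETES, _TL_PAIR2ZYG, _TL_VIABLE, _TL_COPIES = _two_locus_tables()


def step_two_locus(state: PopulationState, s: float) -> PopulationState:
    """One generation of the two-locus engineered-underdominance model.

    Gametes assort independently at the two unlinked loci; zygotes with
    at least one copy of one construct and none of the other are killed
    by the unsuppressed lethal; survivors are weighted by the additive
    cost ``1 - s*c/4`` (``c`` = construct alleles carried, 0-4) and
    renormalized.
    """
    x = _check_state(state, System.TWO_LOCUS_UD)
    if not (0.0 <= s < 1.0):
        raise ValueError(f"fitness cost must be in [0, 1); got {s}")
    gam = x @ _TL_GAMETES  # pooled gamete frequencies (4,)
    pair = np.outer(gam, gam)
    zyg = np.zeros(9)
    np.add.at(zyg, _TL_PAIR2ZYG.ravel(), pair.ravel())
    zyg *= _TL_VIABLE * (1.0 - s * _TL_COPIES / 4.0)
    zyg /= zyg.sum()
    return PopulationState(System.TWO_LOCUS_UD, zyg, state.generation + 1)


def step_state(spec: DriveSystemSpec, state: PopulationState) -> PopulationState:
    """Advance any system's state by one generation."""
    if spec.system is System.EXTREME_UD:
        p = step_extreme_ud(state.frequencies[0], spec.fitness_cost)
        return PopulationState(System.EXTREME_UD, [p, 1.0 - p], state.generation + 1)
    if spec.system is System.TRANSLOCATION:
        return step_translocation(state, spec.fitness_cost)
    return step_two_locus(state, spec.fitness_cost)


def carrier_frequency(state: PopulationState) -> float:
    """Combined frequency of genotypes carrying >= 1 construct allele."""
    copies = np.array(_COPIES[state.system])
    return float(state.frequencies[copies > 0].sum())


class Fate(str, enum.Enum):
    FIXED = "fixed"
    LOST = "lost"
    PERSISTING = "persisting"


@dataclass(frozen=True)
class Trajectory:
    """A deterministic trajectory with its fate classification.

    The fate is read off the final state: FIXED if the carrier frequency
    is at least ``1 - fix_tol``, LOST if at most ``loss_tol``, otherwise
    PERSISTING (ties at the tolerances count as resolved; a trajectory
    parked exactly at the unstable threshold is PERSISTING).
    """

    states: tuple[PopulationState, ...]
    fix_tol: float = 1e-3
    loss_tol: float = 1e-6
    fate: Fate = field(init=False)

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("trajectory requires at least one state")
        final = carrier_frequency(self.states[-1])
        if final >= 1.0 - self.fix_tol:
            fate = Fate.FIXED
        elif final <= self.loss_tol:
            fate = Fate.LOST
        else:
            fate = Fate.PERSISTING
        object.__setattr__(self, "fate", fate)

    def carrier_frequencies(self) -> np.ndarray:
        return np.array([carrier_frequency(s) for s in self.states])

    def __len__(self) -> int:
        return len(self.states)


def iterate(
    spec: DriveSystemSpec,
    state0: PopulationState,
    generations: int,
    fix_tol: float = 1e-3,
    loss_tol: float = 1e-6,
) -> Trajectory:
    """Iterate the system's one-generation map from ``state0``.

    Returns a trajectory of ``generations + 1`` states (including the
    initial one) with its fate classification.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    states = [state0]
    for _ in range(generations):
        states.append(step_state(spec, states[-1]))
    return Trajectory(tuple(states), fix_tol=fix_tol, loss_tol=loss_tol)
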