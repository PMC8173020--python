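"""Two-population and source-sink dynamics under migration.

Underdominant drives are attractive for *local* population replacement
because their threshold behavior confines them: a construct fixed in one
deme leaks into a neighbor only up to a low stable frequency, and
migration itself has a critical rate above which inward wildtype flow
dilutes the construct out of the released deme.

Two demes of equal size exchange a fraction ``m`` of individuals per
generation ("per individual per generation" = probability each
individual migrates).  Event order within a generation: adults migrate,
then each deme mates and censuses offspring.  The source model instead
holds an external population fixed for the construct and sends one-way
migrants into a sink.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .systems import (
    DriveSystemSpec,
    PopulationState,
    System,
    carrier_frequency,
    release_state,
    step_state,
)
from .thresholds import NoThresholdError, analytic_threshold_extreme_ud, release_threshold

__all__ = [
    "TwoPopulationState",
    "MigrationOutcome",
    "ConvergenceError",
    "step_two_population",
    "step_source_sink",
    "sink_equilibrium_frequency",
    "migration_loss_threshold",
]


class ConvergenceError(RuntimeError):
    """The two-deme dynamics did not reach equilibrium within the horizon."""


@dataclass(frozen=True)
class TwoPopulationState:
    """Genotype frequencies of two demes linked by reciprocal migration."""

    state_a: PopulationState
    state_b: PopulationState
    migration_rate: float

    def __post_init__(self) -> None:
        if self.state_a.system is not self.state_b.system:
            raise ValueError("both demes must use the same drive system")
        m = self.migration_rate
        if not (0.0 <= m <= 0.5):
            raise ValueError(
                f"migration rate must be in [0, 0.5] (reciprocal exchange); got {m}"
            )


def _mix(a: np.ndarray, b: np.ndarray, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Reciprocal migration of adults; conserves allele counts exactly."""
    return (1.0 - m) * a + m * b, (1.0 - m) * b + m * a


def step_two_population(tp: TwoPopulationState, spec: DriveSystemSpec) -> TwoPopulationState:
    """Advance both demes one generation: migrate adults, then reproduce."""
    system = tp.state_a.system
    if spec.system is not system:
        raise ValueError(f"spec is for {spec.system.value}, state for {system.value}")
    a, b = _mix(tp.state_a.frequencies, tp.state_b.frequencies, tp.migration_rate)
    gen = tp.state_a.generation
    next_a = step_state(spec, PopulationState(system, a, gen))
    next_b = step_state(spec, PopulationState(system, b, gen))
    return replace(tp, state_a=next_a, state_b=next_b)


def step_source_sink(sink: PopulationState, m: float, spec: DriveSystemSpec) -> PopulationState:
    """One generation of the source model.

    The source is held fixed for the construct; a fraction ``m`` of the
    sink is replaced by construct homozygotes each generation, then the
    sink reproduces.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"one-way migration rate must be in [0, 1]; got {m}")
    source = release_state(sink.system, 1.0).frequencies
    mixed = (1.0 - m) * sink.frequencies + m * source
    if m == 1.0:
        # fully replaced by the source before any mating
        return PopulationState(sink.system, mixed, sink.generation + 1)
    return step_state(spec, PopulationState(sink.system, mixed, sink.generation))


def _run_two_pop(
    spec: DriveSystemSpec,
    state_a: PopulationState,
    state_b: PopulationState,
    m: float,
    horizon: int,
    tol: float = 1e-12,
) -> tuple[PopulationState, PopulationState, bool]:
    tp = TwoPopulationState(state_a, state_b, m)
    for _ in range(horizon):
        nxt = step_two_population(tp, spec)
        delta = max(
            np.max(np.abs(nxt.state_a.frequencies - tp.state_a.frequencies)),
            np.max(np.abs(nxt.state_b.frequencies - tp.state_b.frequencies)),
        )
        tp = nxt
        if delta < tol:
            return tp.state_a, tp.state_b, True
    return tp.state_a, tp.state_b, False


def sink_equilibrium_frequency(
    spec: DriveSystemSpec,
    m: float,
    release_a: float,
    horizon: int = 2000,
) -> float:
    """Long-run construct-carrier frequency in the unreleased deme B.

    Construct homozygotes are released at ``release_a`` in deme A, deme B
    starts wildtype, and the coupled system is iterated until successive
    frequency changes fall below 1e-12.
    """
    system = spec.system
    a, b, converged = _run_two_pop(
        spec, release_state(system, release_a), release_state(system, 0.0), m, horizon
    )
    if not converged:
        raise ConvergenceError(
            f"two-population dynamics not converged after {horizon} generations "
            f"({system.value}, s={spec.fitness_cost}, m={m})"
        )
    return carrier_frequency(b)


class MigrationOutcome(str, enum.Enum):
    CONFINED = "confined"       # fixed in A, persisting at low frequency in B
    LOST_BOTH = "lost_both"     # eliminated from both demes by dilution
    FIXED_BOTH = "fixed_both"   # spreads to fixation in both demes


def _classify(
    spec: DriveSystemSpec, m: float, horizon: int, fix_tol: float, loss_tol: float
) -> MigrationOutcome:
    system = spec.system
    a, b, _ = _run_two_pop(
        spec, release_state(system, 1.0), release_state(system, 0.0), m, horizon
    )
    if carrier_frequency(a) <= loss_tol:
        return MigrationOutcome.LOST_BOTH
    if carrier_frequency(b) >= 1.0 - fix_tol:
        return MigrationOutcome.FIXED_BOTH
    return MigrationOutcome.CONFINED


def migration_loss_threshold(
    spec: DriveSystemSpec,
    release_a: float = 0.6,
    precision: float = 1e-4,
    horizon: int = 2000,
    fix_tol: float = 1e-3,
    loss_tol: float = 1e-6,
) -> tuple[float, MigrationOutcome]:
    """Critical migration rate at which confinement breaks down.

    The confined configuration — construct established (fixed) in deme A
    after a successful release, deme B wildtype — is subjected to
    reciprocal migration at rate ``m`` and iterated to its outcome.  For
    extreme underdominance and translocations the supercritical outcome
    is elimination from both demes (inward wildtype flow dilutes deme A
    below its internal threshold); for the two-locus system it is
    fixation in both demes (its low threshold lets the leak establish).

    Returns the boundary migration rate (bisection on ``m`` in
    ``(0, 0.5]`` to within ``precision``) together with the outcome
    observed just above it.  ``release_a`` must exceed the
    single-population release threshold — otherwise the construct never
    establishes in deme A and no confined state exists.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    # validate that the release can establish the construct in deme A
    if spec.system is System.EXTREME_UD:
        single = analytic_threshold_extreme_ud(spec.fitness_cost)
    else:
        single = release_threshold(spec)
    if release_a <= single:
        raise ValueError(
            f"release_a={release_a} does not exceed the single-population "
            f"threshold {single:.4f}; the construct cannot establish in deme A"
        )
    lo, hi = 0.0, 0.5
    top = _classify(spec, hi, horizon, fix_tol, loss_tol)
    if top is MigrationOutcome.CONFINED:
        raise NoThresholdError(
            f"{spec.system.value} at s={spec.fitness_cost} remains confined "
            f"for all migration rates up to 0.5"
        )
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if _classify(spec, mid, horizon, fix_tol, loss_tol) is MigrationOutcome.CONFINED:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), _classify(spec, hi, horizon, fix_tol, loss_tol)
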