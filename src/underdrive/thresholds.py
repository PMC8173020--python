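"""Release thresholds, maximum invadable fitness cost, and spread speed.

All underdominant systems are bistable: a release of construct
homozygotes below some critical frequency is eliminated, above it the
construct spreads.  For extreme underdominance the threshold has the
closed form ``1 / (2 - s)``; the comparative systems are handled by
bisection on the release fraction over deterministic trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .systems import (
    DriveSystemSpec,
    Fate,
    System,
    carrier_frequency,
    iterate,
    release_state,
    step_state,
)

__all__ = [
    "NoThresholdError",
    "HorizonExceededError",
    "analytic_threshold_extreme_ud",
    "release_threshold",
    "max_invadable_cost",
    "generations_to_carrier_frequency",
]

#: Fate horizon (generations) used when classifying a release outcome.
DEFAULT_HORIZON = 500
#: Bisection precision on release fractions and fitness costs.
DEFAULT_PRECISION = 1e-4


class NoThresholdError(ValueError):
    """The system cannot spread at this fitness cost (no LOST/FIXED switch)."""


class HorizonExceededError(RuntimeError):
    """The requested frequency was not reached within the horizon."""


def analytic_threshold_extreme_ud(s: float) -> float:
    """Unstable equilibrium ``1 / (2 - s)`` of the extreme-UD recursion.

    This is the critical release frequency: above it the construct
    deterministically fixes, below it it is eliminated.
    """
    if not (0.0 <= s < 1.0):
        raise ValueError(f"fitness cost must be in [0, 1); got {s}")
    return 1.0 / (2.0 - s)


def _release_fate(
    spec: DriveSystemSpec, release: float, horizon: int, fix_tol: float, loss_tol: float
) -> Fate:
    traj = iterate(spec, release_state(spec.system, release), horizon,
                   fix_tol=fix_tol, loss_tol=loss_tol)
    return traj.fate


def release_threshold(
    spec: DriveSystemSpec,
    precision: float = DEFAULT_PRECISION,
    horizon: int = DEFAULT_HORIZON,
    fix_tol: float = 1e-3,
    loss_tol: float = 1e-6,
) -> float:
    """Critical release fraction separating elimination from spread.

    Bisects the release fraction of construct homozygotes into an
    otherwise wildtype population; returns the switch point between the
    LOST and FIXED basins to within ``precision``.

    Raises
    ------
    NoThresholdError
        If even a near-total release fails to fix within the horizon
        (the system cannot spread at this fitness cost).
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    # probe just below saturation: f = 1 exactly is trivially absorbing
    # (a monomorphic construct population) even when the system cannot
    # invade, so the no-spread guard must test the open limit f -> 1
    lo, hi = 0.0, 1.0 - min(precision, 1e-4)
    if _release_fate(spec, hi, horizon, fix_tol, loss_tol) is not Fate.FIXED:
        raise NoThresholdError(
            f"{spec.system.value} at s={spec.fitness_cost} does not fix even "
            f"from release 1.0 within {horizon} generations"
        )
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if _release_fate(spec, mid, horizon, fix_tol, loss_tol) is Fate.LOST:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _establishes(
    system: System, s: float, horizon: int, release: float = 1.0 - 1e-6
) -> bool:
    """Does a near-saturation release persist (final carriers >= 1/2)?

    Persistence rather than strict fixation is the relevant criterion:
    the two-locus system holds a stable polymorphic equilibrium with a
    high carrier frequency at large costs, and "cannot spread" means the
    construct is eliminated, not that fixation is incomplete.
    """
    spec = DriveSystemSpec(system, s)
    state = release_state(system, release)
    for _ in range(horizon):
        state = step_state(spec, state)
    return carrier_frequency(state) >= 0.5


def max_invadable_cost(
    system: System,
    precision: float = DEFAULT_PRECISION,
    horizon: int = 1000,
) -> float:
    """Supremum of fitness costs at which the system can still spread.

    Bisects over ``s``, testing whether a near-saturation release
    establishes.  Returns ``1.0`` when spread is possible for every
    ``s < 1`` (extreme underdominance: the threshold ``1/(2-s)`` stays
    below 1 for all admissible costs, so no finite bound exists).
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    system = System(system)
    lo, hi = 0.0, 1.0 - precision
    if _establishes(system, hi, horizon):
        return 1.0  # unbounded below s = 1
    if not _establishes(system, lo, horizon):
        raise NoThresholdError(f"{system.value} cannot spread even at zero cost")
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if _establishes(system, mid, horizon):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generations_to_carrier_frequency(
    spec: DriveSystemSpec,
    release: float,
    target: float,
    horizon: int = DEFAULT_HORIZON,
) -> int:
    """Smallest generation at which the carrier frequency reaches ``target``.

    Counts generations after a release of construct homozygotes at the
    given fraction (generation 0 is the release itself).
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target frequency must be in (0, 1)")
    state = release_state(spec.system, release)
    for k in range(horizon + 1):
        if carrier_frequency(state) >= target:
            return k
        state = step_state(spec, state)
    raise HorizonExceededError(
        f"carrier frequency {target} not reached within {horizon} generations "
        f"from release {release} ({spec.system.value}, s={spec.fitness_cost})"
    )
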