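"""Containers for cage-experiment count data.

A cage experiment tracks, per discrete generation, how many individuals
are construct homozygotes (scored by their fluorescent marker, "CFP+")
versus wildtype ("CFP-").  Generation 0 records the release itself and
defines the initial frequency of each experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CageObservation", "Experiment", "ExperimentSet"]

CAGE_COLUMNS = (
    "experiment_id",
    "release_frequency",
    "generation",
    "count_construct",
    "count_wildtype",
)


@dataclass(frozen=True)
class CageObservation:
    """Counts for one experiment at one generation."""

    experiment_id: int
    generation: int
    count_construct: int
    count_wildtype: int

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.count_construct < 0 or self.count_wildtype < 0:
            raise ValueError("counts must be non-negative")
        if self.count_construct + self.count_wildtype == 0:
            raise ValueError(
                f"experiment {self.experiment_id}, generation {self.generation}: "
                "at least one individual required"
            )

    @property
    def total(self) -> int:
        return self.count_construct + self.count_wildtype

    @property
    def frequency(self) -> float:
        return self.count_construct / self.total


@dataclass(frozen=True)
class Experiment:
    """One cage: consecutive generation counts starting at generation 0."""

    experiment_id: int
    release_frequency: float
    observations: tuple[CageObservation, ...]

    def __post_init__(self) -> None:
        gens = [o.generation for o in self.observations]
        if not gens or gens[0] != 0:
            raise ValueError(
                f"experiment {self.experiment_id}: a generation-0 record is "
                "required (it specifies the initial condition)"
            )
        if gens != list(range(len(gens))):
            raise ValueError(
                f"experiment {self.experiment_id}: generations must be "
                f"consecutive from 0; got {gens}"
            )

    @property
    def n_generations(self) -> int:
        """Number of post-release generations observed."""
        return len(self.observations) - 1

    @property
    def initial_frequency(self) -> float:
        return self.observations[0].frequency

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        tt = np.array([o.count_construct for o in self.observations])
        wt = np.array([o.count_wildtype for o in self.observations])
        return tt, wt


@dataclass(frozen=True)
class ExperimentSet:
    """A collection of cage experiments analysed jointly."""

    experiments: tuple[Experiment, ...]

    def __post_init__(self) -> None:
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate experiment ids: {sorted(ids)}")

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.experiment_id, e.release_frequency, o.generation,
             o.count_construct, o.count_wildtype)
            for e in self.experiments
            for o in e.observations
        ]
        return pd.DataFrame(rows, columns=list(CAGE_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExperimentSet":
        experiments = []
        for eid, grp in frame.groupby("experiment_id", sort=True):
            grp = grp.sort_values("generation")
            obs = tuple(
                CageObservation(int(eid), int(r.generation),
                                int(r.count_construct), int(r.count_wildtype))
                for r in grp.itertuples()
            )
            release = float(grp["release_frequency"].iloc[0])
            experiments.append(Experiment(int(eid), release, obs))
        return cls(tuple(experiments))
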