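"""Reading and writing the cage-count CSV schema and trajectory tables.

Cage CSV columns: ``experiment_id, release_frequency, generation,
count_construct, count_wildtype`` — one row per cage per generation,
generation 0 (the release) required for every experiment.  Trajectory
CSVs carry one row per generation with a column per genotype plus the
carrier frequency.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cage_data import CAGE_COLUMNS, ExperimentSet
from .systems import Trajectory, carrier_frequency

__all__ = ["read_cage_csv", "write_cage_csv", "write_trajectory_csv"]


class CageFormatError(ValueError):
    """Malformed cage CSV content."""


def read_cage_csv(path: str | Path) -> ExperimentSet:
    """Read an :class:`ExperimentSet` from a cage CSV file.

    Malformed rows are reported with their line numbers; a missing
    generation-0 record for any experiment is fatal.
    """
    frame = pd.read_csv(path)
    missing = set(CAGE_COLUMNS) - set(frame.columns)
    if missing:
        raise CageFormatError(f"{path}: missing columns {sorted(missing)}")
    bad_lines = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            if row[list(CAGE_COLUMNS)].isna().any():
                raise ValueError("missing cell")
            for col in ("experiment_id", "generation", "count_construct", "count_wildtype"):
                if float(row[col]) != int(row[col]):
                    raise ValueError(f"{col} must be an integer")
            if int(row["generation"]) < 0 or int(row["count_construct"]) < 0 \
                    or int(row["count_wildtype"]) < 0:
                raise ValueError("negative value")
        except (ValueError, TypeError) as err:
            bad_lines.append(f"line {line}: {err}")
    if bad_lines:
        raise CageFormatError(f"{path}: " + "; ".join(bad_lines))
    for eid, grp in frame.groupby("experiment_id"):
        if 0 not in set(grp["generation"].astype(int)):
            raise CageFormatError(
                f"{path}: experiment {int(eid)} lacks a generation-0 record"
            )
    return ExperimentSet.from_frame(frame)


def write_cage_csv(data: ExperimentSet, path: str | Path) -> Path:
    """Write an :class:`ExperimentSet` to the cage CSV schema."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    return path


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Write a deterministic trajectory: generation, genotypes, carriers."""
    path = Path(path)
    labels = traj.states[0].labels
    rows = [
        {"generation": st.generation,
         **{lab: st.frequencies[i] for i, lab in enumerate(labels)},
         "carrier_frequency": carrier_frequency(st)}
        for st in traj.states
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
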