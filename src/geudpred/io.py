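"""CSV dialects for DVH cohorts and injury labels.

DVH file: one row per dose edge, columns ``patient_id, structure, dose_gy,
volume_cc`` with a mandatory header, UTF-8.  ``structure`` is one of
``brain``, ``left_half``, ``right_half``; volumes are absolute cc.

Labels file: ``patient_id, structure, injury`` with injury in {0, 1}.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .dvh import CumulativeDVH, DVHValidationError
from .synth import STRUCTURE_BRAIN, STRUCTURE_LEFT, STRUCTURE_RIGHT, StructureObservation

__all__ = [
    "CohortFormatError",
    "DVH_COLUMNS",
    "LABEL_COLUMNS",
    "STRUCTURES",
    "write_cohort",
    "read_cohort",
]

DVH_COLUMNS = ["patient_id", "structure", "dose_gy", "volume_cc"]
LABEL_COLUMNS = ["patient_id", "structure", "injury"]
STRUCTURES = (STRUCTURE_BRAIN, STRUCTURE_LEFT, STRUCTURE_RIGHT)


class CohortFormatError(ValueError):
    """A cohort CSV violates the documented dialect."""


def write_cohort(
    observations: Iterable[StructureObservation],
    dvh_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Serialize a cohort to the DVH CSV and labels CSV dialects."""
    obs = list(observations)
    dvh_rows = []
    label_rows = []
    for o in obs:
        for d, v in zip(o.dvh.dose_edges, o.dvh.volume_cc):
            dvh_rows.append((o.patient_id, o.structure, d, v))
        label_rows.append((o.patient_id, o.structure, o.injury))
    pd.DataFrame(dvh_rows, columns=DVH_COLUMNS).to_csv(
        dvh_path, index=False, float_format="%.12g"
    )
    pd.DataFrame(label_rows, columns=LABEL_COLUMNS).to_csv(
        labels_path, index=False
    )


def _check_columns(frame: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")


def read_cohort(
    dvh_path: str | Path, labels_path: str | Path
) -> list[StructureObservation]:
    """Read a cohort from the DVH + labels CSV pair.

    Malformed rows raise :class:`CohortFormatError` naming the file and the
    offending line; patients missing a structure's label are an error, not
    a silent drop.
    """
    dvh_path = Path(dvh_path)
    labels_path = Path(labels_path)
    try:
        dvh = pd.read_csv(dvh_path)
        labels = pd.read_csv(labels_path)
    except FileNotFoundError as exc:
        raise CohortFormatError(str(exc)) from exc
    _check_columns(dvh, DVH_COLUMNS, dvh_path)
    _check_columns(labels, LABEL_COLUMNS, labels_path)

    bad = ~dvh["structure"].isin(STRUCTURES)
    if bad.any():
        line = int(dvh.index[bad][0]) + 2  # header is line 1
        raise CohortFormatError(
            f"{dvh_path}: line {line}: unknown structure "
            f"{dvh.loc[dvh.index[bad][0], 'structure']!r}"
        )
    bad = ~labels["injury"].isin((0, 1))
    if bad.any():
        line = int(labels.index[bad][0]) + 2
        raise CohortFormatError(
            f"{labels_path}: line {line}: injury must be 0 or 1"
        )

    label_map = {
        (str(r.patient_id), r.structure): int(r.injury)
        for r in labels.itertuples()
    }
    observations = []
    for (pid, structure), group in dvh.groupby(
        ["patient_id", "structure"], sort=True
    ):
        pid = str(pid)
        group = group.sort_values("dose_gy")
        try:
            cdvh = CumulativeDVH(
                group["dose_gy"].to_numpy(dtype=float),
                group["volume_cc"].to_numpy(dtype=float),
            )
        except DVHValidationError as exc:
            raise CohortFormatError(
                f"{dvh_path}: invalid DVH for patient {pid!r} "
                f"structure {structure!r}: {exc}"
            ) from exc
        key = (pid, structure)
        if key not in label_map:
            raise CohortFormatError(
                f"{labels_path}: no injury label for patient {pid!r} "
                f"structure {structure!r}"
            )
        observations.append(
            StructureObservation(pid, structure, cdvh, label_map[key])
        )
    if not observations:
        raise CohortFormatError(f"{dvh_path}: no observations found")
    return observations
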