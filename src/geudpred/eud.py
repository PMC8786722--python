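"""Generalized equivalent uniform dose (gEUD) and the metric matrix.

The gEUD reduces a differential DVH to a single dose via the weighted power
mean ``EUD = (sum_i v_i D_i^a)^(1/a)``, where ``v_i`` is the relative
volume of bin ``i``, ``D_i`` its dose, and ``a`` the volume-effect
parameter: ``a = 1`` gives the mean dose (parallel-like behaviour), large
``a`` approaches the maximum dose (series-like behaviour).

The *critical-dose-volume* variant ``EUD_V_D`` applies the same reduction
to only the subvolume covered by doses >= D, with weights renormalized
within that subvolume, so that the reduction is insensitive to how much
low-dose volume the structure happens to contain.

``build_metric_matrix`` evaluates the whole family of candidate predictors
(EUD_V_D over a grid of thresholds D and exponents a, plus the simple point
metrics D_V and V_D) for every structure observation of a cohort.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dvh import (
    CumulativeDVH,
    DVHValidationError,
    cumulative_to_differential,
    dose_at_volume,
    max_dose,
    restrict_above_dose,
    volume_at_dose,
)

__all__ = [
    "EudGrid",
    "ColumnMeta",
    "MetricMatrix",
    "compute_eud",
    "compute_eud_profile",
    "eud_of_restricted",
    "build_metric_matrix",
    "default_dv_volumes",
    "default_vd_doses",
]


def _float_grid(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 9)


def default_dv_volumes() -> np.ndarray:
    """Scan volumes for the D_V family: 0 to 5 cc per 0.5 cc."""
    return _float_grid(0.0, 5.0, 0.5)


def default_vd_doses() -> np.ndarray:
    """Scan doses for the V_D family: 40 to 75 Gy per 1 Gy."""
    return _float_grid(40.0, 75.0, 1.0)


@dataclasses.dataclass(frozen=True)
class EudGrid:
    """Search grid for the EUD_V_D family.

    ``a_values`` defaults to 1..30 in steps of 0.5 (half-integer resolution
    is needed to resolve optima between integers); ``threshold_doses``
    defaults to 0..70 Gy per 5 Gy.
    """

    a_values: np.ndarray = dataclasses.field(
        default_factory=lambda: _float_grid(1.0, 30.0, 0.5)
    )
    threshold_doses: np.ndarray = dataclasses.field(
        default_factory=lambda: _float_grid(0.0, 70.0, 5.0)
    )

    def __post_init__(self) -> None:
        a = np.asarray(self.a_values, dtype=float)
        d = np.asarray(self.threshold_doses, dtype=float)
        if a.size == 0 or np.any(a <= 0) or np.any(np.diff(a) <= 0):
            raise ValueError("a_values must be positive and strictly ascending")
        if d.size == 0 or np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError(
                "threshold_doses must be non-negative and strictly ascending"
            )
        a.flags.writeable = False
        d.flags.writeable = False
        object.__setattr__(self, "a_values", a)
        object.__setattr__(self, "threshold_doses", d)


def compute_eud(ddvh, a: float) -> float:
    """Generalized EUD of a differential DVH at volume-effect parameter ``a``.

    The weighted power mean of the bin doses.  An empty DVH (no volume)
    returns 0 Gy by convention, so that every observation stays scoreable
    when a dose-threshold restriction removes the whole structure.
    """
    if a <= 0:
        raise ValueError("volume-effect parameter a must be positive")
    if ddvh.is_empty:
        return 0.0
    w = ddvh.relative_weights()
    d = ddvh.bin_dose
    dmax = float(d[w > 0].max())
    if dmax <= 0:
        return 0.0
    # Scale by the hottest bin so d/dmax <= 1 and large exponents stay finite.
    return dmax * float(np.dot(w, (d / dmax) ** a)) ** (1.0 / a)


def compute_eud_profile(ddvh, a_values: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`compute_eud` over a grid of ``a`` values."""
    a = np.asarray(a_values, dtype=float)
    if np.any(a <= 0):
        raise ValueError("volume-effect parameter a must be positive")
    if ddvh.is_empty:
        return np.zeros(a.shape)
    w = ddvh.relative_weights()
    d = ddvh.bin_dose
    dmax = float(d[w > 0].max())
    if dmax <= 0:
        return np.zeros(a.shape)
    x = d / dmax  # (nbins,)
    s = np.power.outer(x, a).T @ w  # (na,)
    return dmax * s ** (1.0 / a)


def eud_of_restricted(cdvh: CumulativeDVH, dose_gy: float, a: float) -> float:
    """EUD_V_D: gEUD of the subvolume covered by doses >= ``dose_gy``.

    Weights are renormalized within the retained subvolume; if V_D = 0 the
    result is 0 Gy (the empty-subvolume convention).
    """
    return compute_eud(restrict_above_dose(cdvh, dose_gy), a)


@dataclasses.dataclass(frozen=True)
class ColumnMeta:
    """Metadata for one metric-matrix column."""

    name: str
    family: str  # "eud_vd" | "d_v" | "v_d"
    unit: str  # "Gy" | "cc"
    threshold_gy: float | None = None
    a: float | None = None
    volume_cc: float | None = None


@dataclasses.dataclass
class MetricMatrix:
    """Observations x dosimetric parameters, with per-column metadata.

    ``values`` is indexed by (patient_id, structure); ``rejects`` lists
    observations whose metrics could not be computed, with the reason —
    they are reported, never silently dropped.
    """

    values: pd.DataFrame
    columns: list[ColumnMeta]
    rejects: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)

    def family(self, family: str) -> pd.DataFrame:
        names = [c.name for c in self.columns if c.family == family]
        return self.values[names]

    def column_meta(self, name: str) -> ColumnMeta:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV plus a JSON sidecar of column metadata."""
        path = Path(path)
        self.values.to_csv(path, float_format="%.12g")
        meta = {
            "columns": [dataclasses.asdict(c) for c in self.columns],
            "rejects": [list(r) for r in self.rejects],
        }
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=1), encoding="utf-8"
        )


def _eud_name(d: float, a: float) -> str:
    return f"EUD_V{d:g}Gy_a{a:g}"


def _dv_name(v: float) -> str:
    return f"D_{v:g}cc"


def _vd_name(d: float) -> str:
    return f"V_{d:g}Gy"


def build_metric_matrix(
    cohort: Iterable,
    grid: EudGrid | None = None,
    dv_volumes: Sequence[float] | None = None,
    vd_doses: Sequence[float] | None = None,
) -> MetricMatrix:
    """Evaluate every candidate predictor for every structure observation.

    Columns, in deterministic order: ``EUD_V_D(a)`` over the grid
    (threshold-major, then ascending ``a``), then ``D_V`` over
    ``dv_volumes`` (``V = 0`` means the maximum dose, the V -> 0 limit),
    then ``V_D`` over ``vd_doses`` (absolute cc).
    """
    grid = grid if grid is not None else EudGrid()
    dv_volumes = (
        np.asarray(dv_volumes, dtype=float)
        if dv_volumes is not None
        else default_dv_volumes()
    )
    vd_doses = (
        np.asarray(vd_doses, dtype=float)
        if vd_doses is not None
        else default_vd_doses()
    )
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")

    columns: list[ColumnMeta] = []
    for d in grid.threshold_doses:
        for a in grid.a_values:
            columns.append(
                ColumnMeta(_eud_name(d, a), "eud_vd", "Gy", threshold_gy=float(d), a=float(a))
            )
    for v in dv_volumes:
        columns.append(ColumnMeta(_dv_name(v), "d_v", "Gy", volume_cc=float(v)))
    for d in vd_doses:
        columns.append(ColumnMeta(_vd_name(d), "v_d", "cc", threshold_gy=float(d)))

    rows: list[np.ndarray] = []
    index: list[tuple[str, str]] = []
    rejects: list[tuple[str, str, str]] = []
    na = grid.a_values.size
    for obs in cohort:
        try:
            cdvh = obs.dvh
            vals = np.empty(len(columns))
            pos = 0
            for d in grid.threshold_doses:
                sub = restrict_above_dose(cdvh, float(d))
                vals[pos : pos + na] = compute_eud_profile(sub, grid.a_values)
                pos += na
            total = cdvh.total_volume_cc
            for v in dv_volumes:
                if v <= 0:
                    vals[pos] = max_dose(cdvh)
                elif v > total:
                    vals[pos] = 0.0  # hottest V exceeds the structure itself
                else:
                    vals[pos] = dose_at_volume(cdvh, float(v))
                pos += 1
            for d in vd_doses:
                vals[pos] = volume_at_dose(cdvh, float(d))
                pos += 1
        except (DVHValidationError, AttributeError) as exc:
            rejects.append((str(obs.patient_id), str(obs.structure), str(exc)))
            continue
        rows.append(vals)
        index.append((obs.patient_id, obs.structure))

    if not rows:
        raise ValueError("no observation in the cohort yielded valid metrics")
    frame = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["patient_id", "structure"]),
        columns=[c.name for c in columns],
    )
    return MetricMatrix(frame, columns, rejects)
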