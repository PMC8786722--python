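"""Dose-volume histogram (DVH) containers, point metrics and conversions.

A cumulative DVH gives, for each dose level, the absolute structure volume
receiving at least that dose; it is the native export of treatment-planning
systems.  The generalized-EUD power mean instead consumes *differential*
bins (volume per dose bin), so this module provides the conversion, linear
interpolation for the classic point metrics ``V_D`` (volume covered by
doses >= D) and ``D_V`` (minimum dose delivered to the hottest V), the
restriction of a DVH to the subvolume covered by at least a threshold dose,
and the linear-quadratic EQD2 fractionation conversion.

Conventions
-----------
* Dose in Gy, absolute volume in cc; relative views are derived on demand.
* Dose edges start at 0 Gy with uniform spacing (default 1 Gy/bin).
* The last differential bin absorbs any residual volume at or above the
  final dose edge, so total volume is conserved exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "DVHValidationError",
    "EmptyDVHError",
    "CumulativeDVH",
    "DifferentialDVH",
    "FractionationScheme",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "volume_at_dose",
    "dose_at_volume",
    "max_dose",
    "restrict_above_dose",
    "mean_dose",
    "eqd2",
]

#: Relative tolerance (times total volume) below which a monotonicity
#: violation in a cumulative curve is treated as floating-point noise and
#: snapped, rather than rejected.
_MONOTONE_RTOL = 1e-9


class DVHValidationError(ValueError):
    """An input DVH violates a structural invariant."""


class EmptyDVHError(ValueError):
    """An operation that needs nonzero volume was given an empty DVH."""


@dataclasses.dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: absolute volume receiving at least each edge dose.

    Parameters
    ----------
    dose_edges
        Dose grid in Gy; strictly increasing, uniform spacing, first edge 0.
    volume_cc
        Absolute volume (cc) receiving >= the corresponding edge dose;
        monotone non-increasing, non-negative.  ``volume_cc[0]`` is the
        total structure volume.
    """

    dose_edges: np.ndarray
    volume_cc: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        vol = np.asarray(self.volume_cc, dtype=float)
        if edges.ndim != 1 or vol.ndim != 1 or edges.shape != vol.shape:
            raise DVHValidationError(
                "dose_edges and volume_cc must be 1-D arrays of equal length"
            )
        if edges.size < 2:
            raise DVHValidationError("a DVH needs at least two dose edges")
        if edges[0] != 0.0:
            raise DVHValidationError("dose grid must start at 0 Gy")
        steps = np.diff(edges)
        if np.any(steps <= 0):
            raise DVHValidationError("dose_edges must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise DVHValidationError("dose_edges must be uniformly spaced")
        if not np.all(np.isfinite(vol)):
            raise DVHValidationError("volume_cc contains non-finite values")
        if np.any(vol < 0):
            idx = int(np.argmax(vol < 0))
            raise DVHValidationError(f"negative volume at edge index {idx}")
        scale = max(float(vol[0]), 1.0)
        rises = np.diff(vol)
        bad = rises > _MONOTONE_RTOL * scale
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise DVHValidationError(
                f"volume_cc increases between edge indices {idx} and {idx + 1}"
            )
        # Snap sub-tolerance floating-point upticks so downstream differences
        # are never negative.
        vol = np.minimum.accumulate(vol)
        edges.flags.writeable = False
        vol.flags.writeable = False
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_cc", vol)

    @property
    def total_volume_cc(self) -> float:
        return float(self.volume_cc[0])

    @property
    def bin_width_gy(self) -> float:
        return float(self.dose_edges[1] - self.dose_edges[0])

    def relative_volume(self) -> np.ndarray:
        """Cumulative curve as a fraction of total volume."""
        total = self.total_volume_cc
        if total <= 0:
            raise EmptyDVHError("structure has zero total volume")
        return self.volume_cc / total


@dataclasses.dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: absolute volume per dose bin, at bin-center doses."""

    bin_dose: np.ndarray
    bin_volume_cc: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.bin_dose, dtype=float)
        vol = np.asarray(self.bin_volume_cc, dtype=float)
        if dose.ndim != 1 or vol.ndim != 1 or dose.shape != vol.shape:
            raise DVHValidationError(
                "bin_dose and bin_volume_cc must be 1-D arrays of equal length"
            )
        if np.any(vol < 0):
            idx = int(np.argmax(vol < 0))
            raise DVHValidationError(f"negative bin volume at index {idx}")
        dose.flags.writeable = False
        vol.flags.writeable = False
        object.__setattr__(self, "bin_dose", dose)
        object.__setattr__(self, "bin_volume_cc", vol)

    @classmethod
    def empty(cls) -> "DifferentialDVH":
        """The DVH of an empty subvolume (zero bins); a valid value."""
        return cls(np.empty(0), np.empty(0))

    @property
    def total_volume_cc(self) -> float:
        return float(self.bin_volume_cc.sum())

    @property
    def is_empty(self) -> bool:
        return self.bin_dose.size == 0 or self.total_volume_cc <= 0.0

    def relative_weights(self) -> np.ndarray:
        """Per-bin relative volumes v_i = dV_i / sum(dV); sums to 1."""
        total = self.total_volume_cc
        if total <= 0:
            raise EmptyDVHError("empty DVH has no relative weights")
        return self.bin_volume_cc / total


@dataclasses.dataclass(frozen=True)
class FractionationScheme:
    """Fractionation and tissue sensitivity for the EQD2 conversion.

    ``alpha_beta_gy`` defaults to 3 Gy, the conventional late-responding
    CNS value; ``n_fractions`` defaults to the 31-fraction IMRT schedule.
    """

    n_fractions: int = 31
    alpha_beta_gy: float = 3.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise DVHValidationError("n_fractions must be >= 1")
        if self.alpha_beta_gy <= 0:
            raise DVHValidationError("alpha/beta ratio must be positive")


def cumulative_to_differential(cdvh: CumulativeDVH) -> DifferentialDVH:
    """Difference a cumulative DVH into per-bin volumes at bin centers.

    Bin ``i`` spans ``[edge_i, edge_{i+1})`` and holds
    ``volume_cc[i] - volume_cc[i+1]``; the last bin additionally keeps any
    residual volume at or above the final edge, so the bin volumes sum to
    the total structure volume exactly.
    """
    edges = cdvh.dose_edges
    vol = cdvh.volume_cc
    dv = -np.diff(vol)
    dv[-1] += vol[-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DifferentialDVH(centers, dv)


def differential_to_cumulative(
    ddvh: DifferentialDVH, dose_edges: np.ndarray
) -> CumulativeDVH:
    """Rebuild the cumulative curve as suffix sums of the bin volumes.

    Exact inverse of :func:`cumulative_to_differential` whenever the source
    curve reaches zero volume at its last edge (no residual tail).
    """
    edges = np.asarray(dose_edges, dtype=float)
    if edges.size != ddvh.bin_volume_cc.size + 1:
        raise DVHValidationError("dose_edges must have one more entry than bins")
    suffix = np.concatenate(
        (np.cumsum(ddvh.bin_volume_cc[::-1])[::-1], [0.0])
    )
    return CumulativeDVH(edges, suffix)


def volume_at_dose(
    cdvh: CumulativeDVH, dose_gy: float, mode: str = "absolute"
) -> float:
    """V_D: structure volume covered by doses >= ``dose_gy``.

    Linear interpolation between bracketing edges; doses beyond the last
    edge return 0.  ``mode="relative"`` divides by the total volume.
    """
    if dose_gy < 0:
        raise DVHValidationError("dose must be non-negative")
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    edges = cdvh.dose_edges
    if dose_gy > edges[-1]:
        v = 0.0
    else:
        v = float(np.interp(dose_gy, edges, cdvh.volume_cc))
    if mode == "relative":
        total = cdvh.total_volume_cc
        if total <= 0:
            raise EmptyDVHError("relative volume undefined for empty structure")
        v /= total
    return v


def dose_at_volume(cdvh: CumulativeDVH, volume_cc: float) -> float:
    """D_V: minimum dose delivered to the hottest ``volume_cc`` of the structure.

    Inverse linear interpolation on the cumulative curve.  On a flat segment
    equal to ``volume_cc`` the highest dose attaining >= V is returned (the
    conservative choice for injury prediction).
    """
    total = cdvh.total_volume_cc
    if volume_cc <= 0:
        raise DVHValidationError("volume must be positive")
    if volume_cc > total * (1 + 1e-12):
        raise DVHValidationError(
            f"volume {volume_cc} cc exceeds total structure volume {total} cc"
        )
    vol = cdvh.volume_cc
    edges = cdvh.dose_edges
    qualifying = np.nonzero(vol >= volume_cc)[0]
    if qualifying.size == 0:  # only via the total-volume tolerance above
        return 0.0
    i = int(qualifying[-1])
    if vol[i] <= volume_cc or i == vol.size - 1:
        return float(edges[i])
    frac = (vol[i] - volume_cc) / (vol[i] - vol[i + 1])
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def max_dose(cdvh: CumulativeDVH) -> float:
    """Highest dose received by any part of the structure (the V -> 0 limit
    of :func:`dose_at_volume`): the first edge at which the cumulative curve
    reaches zero, or the last edge if it never does."""
    zero = np.nonzero(cdvh.volume_cc <= 0)[0]
    if zero.size == 0:
        return float(cdvh.dose_edges[-1])
    return float(cdvh.dose_edges[int(zero[0])])


def restrict_above_dose(cdvh: CumulativeDVH, dose_gy: float) -> DifferentialDVH:
    """Differential DVH of the subvolume covered by doses >= ``dose_gy``.

    The partial bin containing the threshold is split by linear
    interpolation of the cumulative curve; zero-volume bins are pruned.  An
    empty result (V_D = 0) is a valid value, not an error; its relative
    weights are undefined but its EUD is defined downstream as 0 Gy.
    """
    if dose_gy < 0:
        raise DVHValidationError("threshold dose must be non-negative")
    v_d = volume_at_dose(cdvh, dose_gy)
    if v_d <= 0:
        return DifferentialDVH.empty()
    edges = cdvh.dose_edges
    vol = cdvh.volume_cc
    if dose_gy >= edges[-1]:
        # Residual volume at/above the final edge; all of it qualifies.
        return DifferentialDVH(np.array([edges[-1]]), np.array([v_d]))
    full = cumulative_to_differential(cdvh)
    k = int(np.searchsorted(edges, dose_gy, side="right")) - 1
    doses = full.bin_dose[k:].copy()
    vols = full.bin_volume_cc[k:].copy()
    # Split the bin containing the threshold: keep V(D) - V(next edge),
    # centred on the retained sub-interval.
    kept = v_d - vol[k + 1]
    if k == vol.size - 2:
        kept += vol[-1]  # residual tail lives in the last bin
    vols[0] = max(kept, 0.0)
    doses[0] = 0.5 * (dose_gy + edges[k + 1])
    mask = vols > 0
    return DifferentialDVH(doses[mask], vols[mask])


def mean_dose(ddvh: DifferentialDVH) -> float:
    """Volume-weighted mean dose, sum(v_i * D_i); equals the gEUD at a = 1."""
    if ddvh.is_empty:
        raise EmptyDVHError("mean dose undefined for an empty DVH")
    return float(np.dot(ddvh.relative_weights(), ddvh.bin_dose))


def eqd2(total_dose_gy: float, scheme: FractionationScheme) -> float:
    """Equivalent dose in 2-Gy fractions under the linear-quadratic model.

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta), with dose per fraction
    d = D / n_fractions.  Doses delivered at exactly 2 Gy/fraction map to
    themselves.
    """
    if total_dose_gy < 0:
        raise DVHValidationError("total dose must be non-negative")
    ab = scheme.alpha_beta_gy
    d = total_dose_gy / scheme.n_fractions
    return total_dose_gy * (d + ab) / (2.0 + ab)
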