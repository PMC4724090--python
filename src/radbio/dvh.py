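"""Dose-volume histogram container, conversions and dose-volume metrics.

A :class:`DoseVolumeHistogram` stores the dose distribution over one
structure either as a *differential* histogram (fraction of the structure
volume in each dose bin) or as a *cumulative* curve (fraction of the
structure receiving at least each bin-edge dose).  All downstream
radiobiology operates on fractional volumes; absolute volumes in cc are
recovered through ``total_volume_cc`` when a constraint needs them.

Conventions
-----------
* Bin edges are strictly increasing and start at 0 Gy.
* Differential volumes attach to bin centers; bins are half-open
  ``[edge_i, edge_{i+1})``.
* Cumulative values are per-edge, non-increasing, start at 1.
* Minimum and maximum dose are reported at bin-edge resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DVHValidationError",
    "DoseVolumeHistogram",
    "FractionationScheme",
    "to_differential",
    "to_cumulative",
    "dose_at_volume",
    "volume_at_dose",
    "absolute_volume_at_dose",
    "summary_metrics",
    "uniform_dvh",
    "dvh_from_dose_list",
]

_EDGE_TOL = 1e-9


class DVHValidationError(ValueError):
    """Raised when a DVH violates its structural invariants."""


@dataclass(frozen=True)
class FractionationScheme:
    """Total dose, number of fractions and the implied dose per fraction.

    The study scheme is 60 Gy in 5 fractions of 12 Gy.
    """

    total_dose_gy: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.n_fractions <= 0 or int(self.n_fractions) != self.n_fractions:
            raise ValueError("n_fractions must be a positive integer")
        if self.total_dose_gy <= 0:
            raise ValueError("total_dose_gy must be positive")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_dose_gy / self.n_fractions


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """Binned dose-versus-volume distribution for one structure.

    Parameters
    ----------
    structure_id:
        Label of the contoured structure (e.g. ``"ptv"``, ``"lung"``).
    dose_edges:
        Strictly increasing bin edges in Gy, first edge 0.
    volume:
        Differential mode: one fractional volume per bin
        (``len(dose_edges) - 1`` values, each >= 0, summing to <= 1).
        Cumulative mode: one value per edge, non-increasing, starting at 1.
    mode:
        ``"differential"`` or ``"cumulative"``.
    total_volume_cc:
        Absolute structure volume; required only for absolute-volume
        constraint checks.
    """

    structure_id: str
    dose_edges: np.ndarray
    volume: np.ndarray
    mode: str
    total_volume_cc: Optional[float] = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume", vol)
        if self.mode not in ("differential", "cumulative"):
            raise DVHValidationError(f"unknown DVH mode {self.mode!r}")
        if edges.ndim != 1 or edges.size < 2:
            raise DVHValidationError("dose_edges must be a 1-d array of >= 2 edges")
        if abs(edges[0]) > _EDGE_TOL:
            raise DVHValidationError("dose_edges must start at 0 Gy")
        if np.any(np.diff(edges) <= 0):
            raise DVHValidationError("dose_edges must be strictly increasing")
        if self.mode == "differential":
            if vol.size != edges.size - 1:
                raise DVHValidationError(
                    "differential DVH needs one volume per bin "
                    f"({edges.size - 1}), got {vol.size}"
                )
            if np.any(vol < -_EDGE_TOL):
                raise DVHValidationError("differential volumes must be >= 0")
            total = float(vol.sum())
            if total > 1 + 1e-9 or total <= 0:
                raise DVHValidationError(
                    f"differential volumes must sum to (0, 1], got {total}"
                )
        else:
            if vol.size != edges.size:
                raise DVHValidationError(
                    "cumulative DVH needs one value per edge "
                    f"({edges.size}), got {vol.size}"
                )
            if np.any(np.diff(vol) > 1e-9):
                raise DVHValidationError("cumulative volumes must be non-increasing")
            if abs(vol[0] - 1.0) > 1e-6:
                raise DVHValidationError("cumulative DVH must start at volume 1")
            if vol[-1] < -_EDGE_TOL:
                raise DVHValidationError("cumulative volumes must end >= 0")
        if self.total_volume_cc is not None and self.total_volume_cc <= 0:
            raise DVHValidationError("total_volume_cc must be positive")

    # -- derived views ---------------------------------------------------

    @property
    def bin_centers(self) -> np.ndarray:
        """Midpoints of the dose bins (differential view)."""
        return 0.5 * (self.dose_edges[:-1] + self.dose_edges[1:])

    def is_normalised(self, tol: float = 1e-6) -> bool:
        """True when the differential volumes sum to 1 within ``tol``."""
        d = to_differential(self)
        return abs(float(d.volume.sum()) - 1.0) <= tol

    def with_scaled_doses(self, factor: float) -> "DoseVolumeHistogram":
        """Return a copy with every dose multiplied by ``factor`` > 0."""
        if factor <= 0:
            raise ValueError("dose scale factor must be positive")
        return replace(self, dose_edges=self.dose_edges * factor)


def to_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a cumulative DVH to differential mode.

    Volumes become successive differences of the cumulative curve; the sum
    of the differential bins equals the initial cumulative value minus the
    final one.  Differential input is returned unchanged.
    """
    if dvh.mode == "differential":
        return dvh
    diff = -np.diff(dvh.volume)
    # cumulative tails >0 leave mass above the last edge unrepresented;
    # that mass is dropped here (the validator bounds it at construction)
    diff = np.clip(diff, 0.0, None)
    return replace(dvh, volume=diff, mode="differential")


def to_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a differential DVH to cumulative mode (reverse cumsum)."""
    if dvh.mode == "cumulative":
        return dvh
    cum = np.concatenate([np.cumsum(dvh.volume[::-1])[::-1], [0.0]])
    # normalise the head to exactly 1 when within tolerance
    if abs(cum[0] - 1.0) <= 1e-9:
        cum[0] = 1.0
    return replace(dvh, volume=cum, mode="cumulative")


def dose_at_volume(dvh: DoseVolumeHistogram, volume_fraction: float) -> float:
    """Dose D such that ``volume_fraction`` of the structure receives >= D.

    ``dose_at_volume(dvh, 0.95)`` is the D95% metric.  Linear interpolation
    between cumulative points; on flat segments the highest dose still
    meeting the fraction is returned.
    """
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume_fraction must lie in (0, 1]")
    cum = to_cumulative(dvh)
    d, c = cum.dose_edges, cum.volume
    meets = np.nonzero(c >= volume_fraction - 1e-12)[0]
    if meets.size == 0:
        # requested coverage larger than the whole recorded curve
        return float(d[0])
    i = meets[-1]
    if i == d.size - 1 or c[i] <= volume_fraction + 1e-12:
        return float(d[i])
    # strictly decreasing segment between i and i+1
    frac = (c[i] - volume_fraction) / (c[i] - c[i + 1])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def volume_at_dose(dvh: DoseVolumeHistogram, dose_gy: float) -> float:
    """Fraction of the structure receiving at least ``dose_gy``."""
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    cum = to_cumulative(dvh)
    return float(np.interp(dose_gy, cum.dose_edges, cum.volume, right=0.0))


def absolute_volume_at_dose(dvh: DoseVolumeHistogram, dose_gy: float) -> float:
    """Absolute volume (cc) receiving at least ``dose_gy``."""
    if dvh.total_volume_cc is None:
        raise DVHValidationError(
            f"structure {dvh.structure_id!r} has no total_volume_cc; "
            "absolute-volume metrics are unavailable"
        )
    return volume_at_dose(dvh, dose_gy) * dvh.total_volume_cc


def summary_metrics(dvh: DoseVolumeHistogram) -> dict:
    """Mean, max, min and D95% dose in Gy.

    Mean is the volume-weighted mean of bin-center doses; max/min are the
    outer edges of the highest/lowest bin with nonzero volume (bin-edge
    resolution, no extrapolation).
    """
    diff = to_differential(dvh)
    v = diff.volume
    total = float(v.sum())
    if total <= 0:
        raise DVHValidationError("empty DVH: no volume in any bin")
    nz = np.nonzero(v > 1e-12)[0]
    return {
        "mean_gy": float(np.dot(v, diff.bin_centers) / total),
        "max_gy": float(diff.dose_edges[nz[-1] + 1]),
        "min_gy": float(diff.dose_edges[nz[0]]),
        "d95_gy": dose_at_volume(dvh, 0.95),
    }


# -- constructors --------------------------------------------------------


def uniform_dvh(
    dose_gy: float,
    structure_id: str = "structure",
    bin_width_gy: float = 0.1,
    total_volume_cc: Optional[float] = None,
) -> DoseVolumeHistogram:
    """Differential DVH of a structure receiving a single uniform dose.

    The whole volume sits in one bin of width ``bin_width_gy`` centred on
    ``dose_gy``; a zero-volume filler bin covers [0, dose - width/2).
    """
    if dose_gy <= 0:
        raise ValueError("dose_gy must be positive")
    h = bin_width_gy / 2.0
    if dose_gy - h <= 0:
        raise ValueError("bin_width_gy too large for this dose")
    edges = np.array([0.0, dose_gy - h, dose_gy + h])
    vol = np.array([0.0, 1.0])
    return DoseVolumeHistogram(structure_id, edges, vol, "differential", total_volume_cc)


def dvh_from_dose_list(
    doses: Sequence[float],
    structure_id: str = "structure",
    total_volume_cc: Optional[float] = None,
    bin_width_gy: float = 1e-3,
) -> DoseVolumeHistogram:
    """Exact differential DVH of an explicit per-voxel dose list.

    Each distinct dose becomes its own narrow bin whose center equals the
    dose exactly, so volume-weighted statistics over the DVH reproduce
    brute-force per-voxel computations to floating-point accuracy.
    Zero-volume filler bins pad the gaps.  All doses must be positive.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list is empty")
    if np.any(doses <= 0):
        raise ValueError("all voxel doses must be positive")
    uniq, counts = np.unique(doses, return_counts=True)
    gaps = np.diff(uniq)
    h = bin_width_gy / 2.0
    if gaps.size:
        h = min(h, float(gaps.min()) / 4.0)
    h = min(h, float(uniq[0]) / 4.0)
    edges = [0.0]
    vols = []
    for d, c in zip(uniq, counts):
        edges.extend([d - h, d + h])
        vols.extend([0.0, c / doses.size])
    return DoseVolumeHistogram(
        structure_id, np.array(edges), np.array(vols), "differential", total_volume_cc
    )
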