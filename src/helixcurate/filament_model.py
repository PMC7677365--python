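"""Filament grouping, ordering, polarity checks and segment windowing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DuplicateRecordError, EmptyInputError
from .star_io import ParticleRecord, ParticleSet

__all__ = [
    "Filament",
    "FilamentTrace",
    "group_filaments",
    "check_polarity_consistency",
    "window_filament",
    "subunits_per_box",
]

# Helical segments refine with tilt near 90 deg; larger deviations mark a
# misaligned particle.
DEFAULT_TILT_GATE = 30.0


@dataclass
class Filament:
    """Ordered particles of one helical tube on one micrograph."""

    micrograph_id: str
    tube_id: int
    particles: list[ParticleRecord]
    order_axis: np.ndarray  # unit 2-vector in the micrograph plane
    consistency: list[bool] = field(default_factory=list)
    inconsistency_reason: list[str] = field(default_factory=list)
    fraction_consistent: float | None = None

    def __post_init__(self):
        if not self.particles:
            raise EmptyInputError("filament with no particles")
        if not self.consistency:
            self.consistency = [True] * len(self.particles)
        if not self.inconsistency_reason:
            self.inconsistency_reason = ["none"] * len(self.particles)

    def __len__(self) -> int:
        return len(self.particles)


@dataclass
class FilamentTrace:
    """Hand-picked filament axis as a polyline on a micrograph."""

    micrograph_id: str
    polyline: np.ndarray  # (n, 2) pixels
    micrograph_width: float
    micrograph_height: float

    def __post_init__(self):
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2:
            raise ConfigurationError("trace polyline needs >= 2 points")
        if self.arc_length() <= 0:
            raise ConfigurationError("trace has zero arc length")

    def arc_length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum()
        )


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant direction of a 2D point cloud (unit vector)."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    return axis / np.linalg.norm(axis)


def group_filaments(particle_set: ParticleSet) -> list[Filament]:
    """Partition particles into filaments and order each along its axis.

    Particles are grouped by (micrograph, tube) and sorted by their
    projection onto the principal axis of the group's coordinates,
    oriented so the first-listed particle projects lowest.  Equal
    projections tie-break by coord_x then coord_y.
    """
    groups: dict[tuple[str, int], list[ParticleRecord]] = {}
    for rec in particle_set:
        groups.setdefault((rec.micrograph_id, rec.tube_id), []).append(rec)

    filaments = []
    for (mic, tube), recs in groups.items():
        coords = np.array([[r.coord_x, r.coord_y] for r in recs])
        seen = set()
        for r in recs:
            key = (r.coord_x, r.coord_y)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate coordinates {key} in tube {tube} of {mic}"
                )
            seen.add(key)
        if len(recs) == 1:
            axis = np.array([1.0, 0.0])
            order = [0]
        else:
            axis = _principal_axis(coords)
            proj = coords @ axis
            if proj[0] > proj.mean():
                # orient so the first-listed particle projects lowest
                axis = -axis
                proj = -proj
            order = sorted(
                range(len(recs)),
                key=lambda i: (proj[i], coords[i, 0], coords[i, 1]),
            )
        filaments.append(Filament(
            micrograph_id=mic,
            tube_id=tube,
            particles=[recs[i] for i in order],
            order_axis=axis,
        ))
    return filaments


def _wrap180(delta: np.ndarray | float):
    """Wrap to (-180, 180]."""
    wrapped = np.asarray(delta, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    return wrapped


def circular_median(angles_deg: np.ndarray) -> float:
    """Sample angle minimizing the summed absolute wrapped deviations."""
    angles = np.asarray(angles_deg, dtype=float)
    costs = [
        np.abs(_wrap180(angles - a)).sum() for a in angles
    ]
    return float(angles[int(np.argmin(costs))])


def check_polarity_consistency(
    filament: Filament,
    psi_tol: float = 15.0,
    tilt_gate: float = DEFAULT_TILT_GATE,
) -> tuple[Filament, float]:
    """Flag polarity flips and misaligned particles.

    A particle is inconsistent when its psi deviates from the filament's
    circular-median psi by more than ``psi_tol`` after wrapping; a
    deviation within ``psi_tol`` of 180 deg is a polarity flip.  Particles
    whose tilt deviates from 90 deg by more than ``tilt_gate`` are flagged
    regardless of psi.  Returns the updated filament and the fraction of
    consistent particles.
    """
    if not 0 < psi_tol < 90:
        raise ConfigurationError("psi_tol must be in (0, 90)")
    n = len(filament.particles)
    if n < 2:
        warnings.warn("singleton filament: polarity check is vacuous")
        filament.consistency = [True]
        filament.inconsistency_reason = ["none"]
        filament.fraction_consistent = 1.0
        return filament, 1.0

    psis = np.array([p.psi for p in filament.particles])
    ref = circular_median(psis)
    dev = np.abs(_wrap180(psis - ref))

    flags, reasons = [], []
    for i, p in enumerate(filament.particles):
        if abs(p.tilt - 90.0) > tilt_gate:
            flags.append(False)
            reasons.append("tilt")
        elif dev[i] > psi_tol:
            flags.append(False)
            reasons.append("flip" if abs(dev[i] - 180.0) <= psi_tol
                           else "inconsistent")
        else:
            flags.append(True)
            reasons.append("none")

    filament.consistency = flags
    filament.inconsistency_reason = reasons
    fraction = float(np.mean(flags))
    filament.fraction_consistent = fraction
    return filament, fraction


def subunits_per_box(box_px: float, step_px: float) -> int:
    """Whole inter-subunit translation steps contained in one box."""
    if box_px <= 0 or step_px <= 0:
        raise ConfigurationError("box and step must be positive")
    return int(box_px // step_px)


def _point_at_arc(polyline: np.ndarray, cumlen: np.ndarray,
                  s: float) -> np.ndarray:
    """Piecewise-linear interpolation of the polyline at arc position s."""
    j = int(np.searchsorted(cumlen, s, side="right")) - 1
    j = min(max(j, 0), len(polyline) - 2)
    seg = polyline[j + 1] - polyline[j]
    seg_len = cumlen[j + 1] - cumlen[j]
    t = 0.0 if seg_len == 0 else (s - cumlen[j]) / seg_len
    return polyline[j] + t * seg


def window_filament(
    trace: FilamentTrace, box_px: float, step_px: float
) -> list[np.ndarray]:
    """Segment centers stepped along the trace at fixed arc intervals.

    Centers start at arc position box_px/2 and advance by step_px while
    the box still fits inside the trace.  Centers whose box would extend
    beyond the micrograph are dropped.
    """
    if box_px <= 0 or step_px <= 0:
        raise ConfigurationError("box and step must be positive")
    if box_px > min(trace.micrograph_width, trace.micrograph_height):
        raise ConfigurationError("box larger than micrograph")

    total = trace.arc_length()
    if total < box_px:
        warnings.warn("trace shorter than the box; no segments generated")
        return []

    diffs = np.linalg.norm(np.diff(trace.polyline, axis=0), axis=1)
    cumlen = np.concatenate([[0.0], np.cumsum(diffs)])

    half = box_px / 2.0
    centers = []
    s = half
    while s <= total - half + 1e-9:
        center = _point_at_arc(trace.polyline, cumlen, s)
        if (half <= center[0] <= trace.micrograph_width - half
                and half <= center[1] <= trace.micrograph_height - half):
            centers.append(center)
        s += step_px
    return centers
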