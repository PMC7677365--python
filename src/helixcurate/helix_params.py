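"""Per-step helical rise/twist estimation and two-stage particle selection.

A "step" is the screw relation between two consecutive particles of a
filament: the axial translation (rise, Å) obtained from the refined
segment centers projected onto the in-plane filament axis, and the
rotation increment (twist, deg) obtained from the difference of the rot
Euler angles.  Dataset statistics over valid steps drive two sequential
gates: an outlier cut at ``sd_mult`` standard deviations, then a
confidence band on the recomputed statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

from .errors import (
    BranchError,
    ConfigurationError,
    EmptyInputError,
)
from .filament_model import Filament
from .star_io import ParticleRecord

__all__ = [
    "HelicalStep",
    "HelicalStats",
    "SelectionReport",
    "wrap_angle",
    "compute_steps",
    "dataset_stats",
    "select_particles",
    "curate_particles",
]


@dataclass
class HelicalStep:
    filament: Filament
    index_pair: tuple[int, int]
    rise: float
    twist: float
    valid: bool = True
    invalid_reason: str = "none"  # flip | tilt | inconsistent | none


@dataclass
class HelicalStats:
    mean_rise: float
    sd_rise: float
    mean_twist: float
    sd_twist: float
    n_steps: int


@dataclass
class SelectionReport:
    # particle id -> keep | removed_outlier | removed_ci | removed_inconsistent
    decisions: dict[int, str]
    particles: dict[int, ParticleRecord]
    step_stage1_removed: list[HelicalStep]
    step_stage2_removed: list[HelicalStep]
    stage1_stats: HelicalStats
    stage2_stats: HelicalStats
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            self.counts = {
                c: sum(1 for d in self.decisions.values() if d == c)
                for c in ("keep", "removed_outlier", "removed_ci",
                          "removed_inconsistent")
            }

    def kept_particles(self) -> list[ParticleRecord]:
        return [self.particles[i] for i, d in self.decisions.items()
                if d == "keep"]


def wrap_angle(delta: float) -> float:
    """Wrap an angle in degrees to the half-open interval (-180, 180]."""
    if not math.isfinite(delta):
        raise ConfigurationError("angle must be finite")
    wrapped = delta % 360.0
    if wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


def _axis_unit(psi_deg: float) -> np.ndarray:
    """In-plane filament axis for angle psi; u(0) = (0, 1), CCW-positive."""
    rad = math.radians(psi_deg)
    return np.array([-math.sin(rad), math.cos(rad)])


def _refined_center(p: ParticleRecord) -> np.ndarray:
    if p.pixel_size is None:
        raise ConfigurationError(
            "pixel size unknown; cannot convert coordinates to Å"
        )
    return (np.array([p.coord_x, p.coord_y]) * p.pixel_size
            - np.array([p.origin_x, p.origin_y]))


def compute_steps(
    filament: Filament,
    expected_twist: float | None = None,
    subunit_steps_per_box_step: int = 1,
) -> list[HelicalStep]:
    """Rise and twist between consecutive particles of one filament.

    The refined center is coordinate x pixel_size minus origin
    (subtractive convention).  Rise is the displacement projected onto
    the in-plane axis implied by the circular mean of the two psis,
    divided by the number of subunit steps separating the boxes.  Twist
    is the wrapped rot difference, re-branched near ``expected_twist``
    when given.  Steps touching a flagged particle are invalid.
    """
    steps: list[HelicalStep] = []
    parts = filament.particles
    flags = filament.consistency
    reasons = filament.inconsistency_reason
    for i in range(len(parts) - 1):
        a, b = parts[i], parts[i + 1]
        if not (flags[i] and flags[i + 1]):
            reason = reasons[i] if not flags[i] else reasons[i + 1]
            if reason == "none":
                reason = "inconsistent"
            steps.append(HelicalStep(
                filament, (i, i + 1), rise=math.nan, twist=math.nan,
                valid=False, invalid_reason=reason,
            ))
            continue
        pa, pb = _refined_center(a), _refined_center(b)
        psi_mean = a.psi + 0.5 * wrap_angle(b.psi - a.psi)
        rise = float((pb - pa) @ _axis_unit(psi_mean))
        rise /= subunit_steps_per_box_step
        twist = wrap_angle(b.rot - a.rot)
        if expected_twist is not None:
            twist = expected_twist + wrap_angle(twist - expected_twist)
        steps.append(HelicalStep(filament, (i, i + 1), rise, twist))
    return steps


def _circular_mean(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))


def dataset_stats(steps: list[HelicalStep]) -> HelicalStats:
    """Mean and sample SD (n-1) of rise and twist over valid steps.

    Twist is averaged on a single wrapped branch centered on the circular
    mean; dispersion beyond 90 deg from that branch is an error.
    """
    valid = [s for s in steps if s.valid]
    if not valid:
        raise EmptyInputError("no valid steps")
    rises = np.array([s.rise for s in valid])
    twists = np.array([s.twist for s in valid])

    cmean = _circular_mean(twists)
    rel = np.array([wrap_angle(t - cmean) for t in twists])
    if np.max(np.abs(rel)) > 90.0:
        raise BranchError(
            "twist values span more than ±90° around their circular mean"
        )
    mean_twist = wrap_angle(cmean + float(rel.mean()))

    def sample_sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    return HelicalStats(
        mean_rise=float(rises.mean()),
        sd_rise=sample_sd(rises),
        mean_twist=mean_twist,
        sd_twist=sample_sd(rel),
        n_steps=len(valid),
    )


def _effective_sd(sd: float, mean: float) -> float:
    # sub-ppm relative dispersion is below the precision of any real
    # metadata (text tables carry ~6 decimals); treat it as exactly zero
    # so that noiseless data passes both gates trivially
    return 0.0 if sd <= 1e-6 * (1.0 + abs(mean)) else sd


def _within(value: float, mean: float, halfwidth: float) -> bool:
    # halfwidth == 0 passes everything (degenerate but well-defined)
    return abs(value - mean) <= halfwidth or halfwidth == 0.0


def _twist_dev(step_twist: float, mean_twist: float) -> float:
    return abs(wrap_angle(step_twist - mean_twist))


def select_particles(
    steps: list[HelicalStep],
    stats: HelicalStats,
    sd_mult: float = 2.0,
    ci_level: float = 0.95,
) -> SelectionReport:
    """Two-stage selection: SD outlier cut, then a confidence band.

    Stage 1 removes valid steps more than ``sd_mult`` SDs from the mean
    in rise OR twist.  Stage 2 recomputes statistics on the survivors and
    keeps steps within mean ± z(ci_level) x SD on both parameters.  A
    particle is kept iff every valid step it touches is kept; particles
    with no valid step are removed as inconsistent.
    """
    if sd_mult <= 0:
        raise ConfigurationError("sd_mult must be positive")
    if not 0 < ci_level < 1:
        raise ConfigurationError("ci_level must be in (0, 1)")

    valid = [s for s in steps if s.valid]
    if not valid:
        raise EmptyInputError("no valid steps")

    sd_rise1 = _effective_sd(stats.sd_rise, stats.mean_rise)
    sd_twist1 = _effective_sd(stats.sd_twist, stats.mean_twist)
    stage1_removed, survivors = [], []
    for s in valid:
        ok = (
            _within(s.rise, stats.mean_rise, sd_mult * sd_rise1)
            and (_twist_dev(s.twist, stats.mean_twist)
                 <= sd_mult * sd_twist1 or sd_twist1 == 0.0)
        )
        (survivors if ok else stage1_removed).append(s)

    if not survivors:
        raise EmptyInputError("stage 1 removed every step")
    stats2 = dataset_stats(survivors)
    z = float(_scipy_stats.norm.ppf(0.5 + ci_level / 2.0))

    sd_rise2 = _effective_sd(stats2.sd_rise, stats2.mean_rise)
    sd_twist2 = _effective_sd(stats2.sd_twist, stats2.mean_twist)
    stage2_removed, kept_steps = [], []
    for s in survivors:
        ok = (
            _within(s.rise, stats2.mean_rise, z * sd_rise2)
            and (_twist_dev(s.twist, stats2.mean_twist)
                 <= z * sd_twist2 or sd_twist2 == 0.0)
        )
        (kept_steps if ok else stage2_removed).append(s)

    # particle-level decisions: AND over adjacent valid steps
    particles: dict[int, ParticleRecord] = {}
    adjacent: dict[int, list[str]] = {}
    has_valid: dict[int, bool] = {}

    def pid(f: Filament, i: int) -> int:
        return id(f.particles[i])

    removed1 = {id(s) for s in stage1_removed}
    removed2 = {id(s) for s in stage2_removed}
    for s in steps:
        for i in s.index_pair:
            key = pid(s.filament, i)
            particles[key] = s.filament.particles[i]
            adjacent.setdefault(key, [])
            has_valid.setdefault(key, False)
            if s.valid:
                has_valid[key] = True
                if id(s) in removed1:
                    adjacent[key].append("outlier")
                elif id(s) in removed2:
                    adjacent[key].append("ci")
                else:
                    adjacent[key].append("keep")

    decisions = {}
    for key in particles:
        if not has_valid[key]:
            decisions[key] = "removed_inconsistent"
        elif "outlier" in adjacent[key]:
            decisions[key] = "removed_outlier"
        elif "ci" in adjacent[key]:
            decisions[key] = "removed_ci"
        else:
            decisions[key] = "keep"

    return SelectionReport(
        decisions=decisions,
        particles=particles,
        step_stage1_removed=stage1_removed,
        step_stage2_removed=stage2_removed,
        stage1_stats=stats,
        stage2_stats=stats2,
    )


def curate_particles(
    particle_set,
    sd_mult: float = 2.0,
    ci_level: float = 0.95,
    psi_tol: float = 15.0,
    expected_twist: float | None = None,
) -> SelectionReport:
    """End-to-end curation of a particle set.

    Groups particles into filaments, flags polarity flips, computes
    helical steps, derives dataset statistics and applies the two-stage
    selection.  Particles that contribute no step (singleton filaments)
    are reported as removed_inconsistent.
    """
    from .filament_model import check_polarity_consistency, group_filaments

    filaments = group_filaments(particle_set)
    steps: list[HelicalStep] = []
    orphans: list[ParticleRecord] = []
    for f in filaments:
        if len(f) < 2:
            orphans.extend(f.particles)
            continue
        check_polarity_consistency(f, psi_tol=psi_tol)
        steps.extend(compute_steps(f, expected_twist=expected_twist))

    stats = dataset_stats(steps)
    report = select_particles(steps, stats, sd_mult=sd_mult,
                              ci_level=ci_level)
    for p in orphans:
        report.particles[id(p)] = p
        report.decisions[id(p)] = "removed_inconsistent"
    report.counts = {
        c: sum(1 for d in report.decisions.values() if d == c)
        for c in ("keep", "removed_outlier", "removed_ci",
                  "removed_inconsistent")
    }
    return report
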