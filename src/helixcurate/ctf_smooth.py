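"""Per-filament defocus smoothing.

Defocus estimated per segment is noisy, but a filament is a continuous
object, so its true defocus varies smoothly along the axis.  Each
particle's mean defocus is therefore re-estimated from a local window of
five filament neighbors: the extreme high and low values are discarded
and a least-squares line through the remaining three is evaluated at the
particle's own arc position.  The astigmatism (defocus_u - defocus_v) and
its angle are left untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EmptyInputError
from .filament_model import Filament
from .star_io import ParticleSet

__all__ = ["SmoothingResult", "trimmed_linefit", "smooth_filament_ctf",
           "smooth_particle_set"]


@dataclass
class SmoothingResult:
    smoothed_u: np.ndarray
    smoothed_v: np.ndarray
    windows: list[list[int]]
    changed: np.ndarray  # bool per particle
    warning: str | None = None
    # RMS deviation of mean defocus from the local fitted lines
    rms_pre: float = 0.0
    rms_post: float = 0.0


def trimmed_linefit(
    points: list[tuple[float, float]], n_remove_extremes: int = 1
) -> tuple[float, float]:
    """Least-squares line after discarding the extreme values.

    Exactly ``n_remove_extremes`` maximum-value and minimum-value points
    are removed (by value, not abscissa); ties remove the later-indexed
    point.  Returns (slope, intercept).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2 * n_remove_extremes + 3:
        raise EmptyInputError(
            f"need at least {2 * n_remove_extremes + 3} points, "
            f"got {pts.shape[0]}"
        )
    x, y = pts[:, 0], pts[:, 1]
    if np.all(y == y[0]):
        return 0.0, float(y[0])
    if np.all(x == x[0]):
        raise ConfigurationError("abscissas all identical")

    keep = np.ones(len(y), dtype=bool)
    for _ in range(n_remove_extremes):
        live = np.nonzero(keep)[0]
        # later-indexed point wins ties
        keep[live[np.nonzero(y[live] == y[live].max())[0][-1]]] = False
        live = np.nonzero(keep)[0]
        keep[live[np.nonzero(y[live] == y[live].min())[0][-1]]] = False

    slope, intercept = np.polyfit(x[keep], y[keep], 1)
    return float(slope), float(intercept)


def _arc_positions(filament: Filament) -> np.ndarray:
    """Cumulative arc position of each particle along the filament (Å)."""
    coords = np.array(
        [[p.coord_x, p.coord_y] for p in filament.particles]
    )
    pix = np.array([
        p.pixel_size if p.pixel_size is not None else 1.0
        for p in filament.particles
    ])
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    steps = steps * 0.5 * (pix[:-1] + pix[1:])
    return np.concatenate([[0.0], np.cumsum(steps)])


def smooth_filament_ctf(
    filament: Filament, window: int = 5
) -> SmoothingResult:
    """Smooth mean defocus along one filament by trimmed local line fits.

    Filaments with fewer particles than the window are returned
    unchanged.  Windows at the filament ends are clamped to the terminal
    ``window`` particles, so the fit extrapolates there.
    """
    if window < 5 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 5")

    n = len(filament.particles)
    u = np.array([p.defocus_u for p in filament.particles])
    v = np.array([p.defocus_v for p in filament.particles])
    mean_d = 0.5 * (u + v)

    if n < window:
        warnings.warn(
            f"filament with {n} < {window} particles left unsmoothed"
        )
        return SmoothingResult(
            smoothed_u=u.copy(), smoothed_v=v.copy(),
            windows=[list(range(n))] * n,
            changed=np.zeros(n, dtype=bool),
            warning="below window size",
        )

    arc = _arc_positions(filament)
    half = window // 2
    fitted = np.empty(n)
    windows = []
    residual_pre = []
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        idx = list(range(lo, lo + window))
        slope, intercept = trimmed_linefit(
            [(arc[j], mean_d[j]) for j in idx]
        )
        fitted[i] = slope * arc[i] + intercept
        windows.append(idx)
        residual_pre.append(mean_d[i] - fitted[i])

    half_astig = 0.5 * (u - v)
    smoothed_u = fitted + half_astig
    smoothed_v = fitted - half_astig
    changed = ~np.isclose(fitted, mean_d, rtol=0, atol=1e-9)

    # post-smoothing residuals against re-fitted local lines
    residual_post = []
    for i, idx in enumerate(windows):
        slope, intercept = trimmed_linefit(
            [(arc[j], fitted[j]) for j in idx]
        )
        residual_post.append(fitted[i] - (slope * arc[i] + intercept))

    return SmoothingResult(
        smoothed_u=smoothed_u, smoothed_v=smoothed_v,
        windows=windows, changed=changed,
        rms_pre=float(np.sqrt(np.mean(np.square(residual_pre)))),
        rms_post=float(np.sqrt(np.mean(np.square(residual_post)))),
    )


def smooth_particle_set(
    particle_set: ParticleSet, window: int = 5
) -> tuple[ParticleSet, list[tuple[Filament, SmoothingResult]]]:
    """Smooth every filament in a particle set; returns a new set.

    Record order of the input is preserved in the output.
    """
    from .filament_model import group_filaments

    filaments = group_filaments(particle_set)
    smoothed: dict[int, tuple[float, float]] = {}
    reports = []
    for f in filaments:
        result = smooth_filament_ctf(f, window=window)
        reports.append((f, result))
        for p, su, sv in zip(f.particles, result.smoothed_u,
                             result.smoothed_v):
            smoothed[id(p)] = (float(su), float(sv))

    new_records = [
        rec.copy(defocus_u=smoothed[id(rec)][0],
                 defocus_v=smoothed[id(rec)][1])
        for rec in particle_set
    ]
    return ParticleSet(new_records, dict(particle_set.provenance)), reports
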