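"""Synthetic particle metadata and toy structures with known ground truth.

The generator lays straight filaments at random in-plane orientations,
steps segment coordinates at a fixed pixel interval and encodes the true
helical rise in the origin shifts, so that the curation pipeline can be
validated against planted labels: gross rise outliers, polarity flips
and defocus spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .star_io import ParticleRecord, ParticleSet

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset",
           "generate_toy_polymer"]

DEFOCUS_SPIKE = 5000.0  # Å added to designated spike particles


@dataclass
class SyntheticConfig:
    n_micrographs: int = 2
    filaments_per_micrograph: int = 3
    particles_per_filament: int = 20
    true_rise: float = 27.17
    true_twist: float = -166.7
    pixel_size: float = 1.045
    box_px: int = 328
    step_px: int = 26
    angular_noise_sd: float = 0.0
    origin_noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_rise_shift: float = 10.0
    flip_fraction: float = 0.0
    defocus_base: float = 15000.0
    defocus_gradient: float = 0.0  # Å per Å of arc
    defocus_spike_fraction: float = 0.0
    astigmatism: float = 100.0
    micrograph_px: int = 4096
    seed: int = 0

    def validate(self) -> None:
        if self.particles_per_filament < 2:
            raise ConfigurationError("particles_per_filament must be >= 2")
        for name in ("outlier_fraction", "flip_fraction",
                     "defocus_spike_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.pixel_size <= 0 or self.true_rise <= 0:
            raise ConfigurationError("scales must be positive")


@dataclass
class GroundTruth:
    # aligned with the generated record order
    particle_labels: list[str]          # clean | outlier | flipped | defocus_spike
    true_defocus: np.ndarray            # mean defocus per particle, Å
    step_rise: np.ndarray               # per generated consecutive pair
    step_twist: np.ndarray
    step_is_outlier: np.ndarray         # bool, aligned with step arrays
    step_filament: list[tuple[str, int]] = field(default_factory=list)


def generate_dataset(cfg: SyntheticConfig) -> tuple[ParticleSet, GroundTruth]:
    """Generate a particle table plus the labels that produced it.

    Filaments are straight; segment coordinates advance by ``step_px``
    pixels while the encoded helical rise per step is ``true_rise`` Å
    (the difference is absorbed into the origin shifts).  An "outlier"
    particle is displaced along the axis by ``outlier_rise_shift`` (as is
    everything downstream of it), so exactly the step entering it is
    perturbed.  Flipped particles have psi + 180 and negated rot.
    Defocus follows base + gradient x arc, with +5000 Å spikes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    records: list[ParticleRecord] = []
    labels: list[str] = []
    true_defocus: list[float] = []
    step_rise: list[float] = []
    step_twist: list[float] = []
    step_outlier: list[bool] = []
    step_filament: list[tuple[str, int]] = []

    step_ang = cfg.step_px * cfg.pixel_size
    n = cfg.particles_per_filament

    for m in range(cfg.n_micrographs):
        mic = f"synthetic_{m:04d}.mrc"
        for tube in range(1, cfg.filaments_per_micrograph + 1):
            theta = rng.uniform(0.0, 360.0)
            # direction of increasing arc; psi chosen so the axis
            # convention u(psi) = (-sin, cos) reproduces it
            direction = np.array([-math.sin(math.radians(theta)),
                                  math.cos(math.radians(theta))])
            psi0 = theta
            margin = cfg.box_px / 2 + 10
            span = (n - 1) * cfg.step_px
            # grow the virtual micrograph if the filament cannot fit
            mic_px = max(cfg.micrograph_px, int(2 * (margin + span) + 100))
            lo, hi = margin + span, mic_px - margin - span
            start = rng.uniform(lo, hi, size=2)

            is_outlier = rng.random(n) < cfg.outlier_fraction
            is_outlier[0] = False  # first particle starts no step
            is_flip = rng.random(n) < cfg.flip_fraction
            is_spike = rng.random(n) < cfg.defocus_spike_fraction

            # cumulative axial shift: outliers displace themselves and
            # everything downstream
            axial_shift = np.cumsum(
                np.where(is_outlier, cfg.outlier_rise_shift, 0.0)
            )
            origin_noise = (
                rng.normal(0.0, cfg.origin_noise_sd, size=(n, 2))
                if cfg.origin_noise_sd > 0 else np.zeros((n, 2))
            )
            ang_noise = (
                rng.normal(0.0, cfg.angular_noise_sd, size=(n, 2))
                if cfg.angular_noise_sd > 0 else np.zeros((n, 2))
            )

            prev_true_pos = None
            prev_rot = None
            for i in range(n):
                coord = start + i * cfg.step_px * direction
                arc = i * step_ang
                # true axial position encodes the helical rise
                true_axial = i * cfg.true_rise + axial_shift[i]
                # origin = coord*pix - refined_center (subtractive)
                offset_along = arc - true_axial
                origin = offset_along * direction + origin_noise[i]

                rot = (i * cfg.true_twist + ang_noise[i, 0]) % 360.0
                psi = psi0 + ang_noise[i, 1]
                label = "clean"
                if is_flip[i]:
                    label = "flipped"
                    psi = psi + 180.0
                    rot = (-rot) % 360.0
                elif is_outlier[i]:
                    label = "outlier"
                elif is_spike[i]:
                    label = "defocus_spike"

                d_true = cfg.defocus_base + cfg.defocus_gradient * arc
                d = d_true + (DEFOCUS_SPIKE if is_spike[i] else 0.0)

                records.append(ParticleRecord(
                    micrograph_id=mic,
                    tube_id=tube,
                    coord_x=float(coord[0]),
                    coord_y=float(coord[1]),
                    psi=float(psi % 360.0),
                    tilt=90.0,
                    rot=float(rot),
                    origin_x=float(origin[0]),
                    origin_y=float(origin[1]),
                    defocus_u=float(d + cfg.astigmatism / 2),
                    defocus_v=float(d - cfg.astigmatism / 2),
                    defocus_angle=0.0,
                    pixel_size=cfg.pixel_size,
                ))
                labels.append(label)
                true_defocus.append(d_true)

                true_pos = coord * cfg.pixel_size - origin
                if i > 0:
                    rise = float((true_pos - prev_true_pos) @ direction)
                    step_rise.append(rise)
                    d_rot = (rot - prev_rot) % 360.0
                    step_twist.append(d_rot - 360.0 if d_rot > 180.0
                                      else d_rot)
                    step_outlier.append(bool(is_outlier[i]))
                    step_filament.append((mic, tube))
                prev_true_pos, prev_rot = true_pos, rot

    truth = GroundTruth(
        particle_labels=labels,
        true_defocus=np.array(true_defocus),
        step_rise=np.array(step_rise),
        step_twist=np.array(step_twist),
        step_is_outlier=np.array(step_outlier, dtype=bool),
        step_filament=step_filament,
    )
    particle_set = ParticleSet(records, {"source": "synthetic",
                                         "seed": cfg.seed})
    return particle_set, truth


# ---------------------------------------------------------------------------
# toy atomic structures

#: asymmetric heavy-atom cluster used as one subunit (name, element, xyz)
_SUBUNIT_TEMPLATE = [
    ("N", "N", (1.5, 0.0, 0.0)),
    ("CA", "C", (2.9, 0.3, 0.2)),
    ("C", "C", (3.6, -0.9, 0.9)),
    ("O", "O", (3.2, -2.05, 0.8)),
    ("CB", "C", (3.4, 1.65, 0.75)),
    ("SG", "S", (5.1, 2.0, 0.4)),
]


def generate_toy_polymer(
    n_subunits: int,
    rise: float,
    twist: float,
    atoms_per_subunit: int | None = None,
    b_factors: list[float] | None = None,
):
    """Helical polymer built by a screw operation on an asymmetric cluster.

    Subunit k (1-based residue number) is the template rotated by
    (k-1) x twist about z and translated by (k-1) x rise along z.
    ``b_factors`` assigns one B value per subunit.
    """
    from .struct_metrics import Atom, Structure

    if n_subunits < 1:
        raise ConfigurationError("n_subunits must be >= 1")
    template = _SUBUNIT_TEMPLATE
    if atoms_per_subunit is not None:
        if not 1 <= atoms_per_subunit <= len(_SUBUNIT_TEMPLATE):
            raise ConfigurationError(
                f"atoms_per_subunit must be in [1, {len(_SUBUNIT_TEMPLATE)}]"
            )
        template = _SUBUNIT_TEMPLATE[:atoms_per_subunit]
    coords = np.array([t[2] for t in template])
    if len(template) > 1 and np.allclose(coords, coords[0]):
        raise ConfigurationError("degenerate subunit cluster")
    if b_factors is not None and len(b_factors) != n_subunits:
        raise ConfigurationError("need one B-factor per subunit")

    atoms = []
    for k in range(n_subunits):
        ang = math.radians(k * twist)
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        shifted = coords @ rot.T + np.array([0.0, 0.0, k * rise])
        b = b_factors[k] if b_factors is not None else 20.0
        for (name, element, _), pos in zip(template, shifted):
            atoms.append(Atom(
                element=element, atom_name=name, residue_name="TOY",
                residue_number=k + 1, chain_id="A",
                position=pos.copy(), b_factor=float(b), occupancy=1.0,
            ))
    return Structure(atoms=atoms, source="generate_toy_polymer")
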