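"""Reading and writing particle metadata tables (STAR dialect).

Only a single particle loop is supported.  Column names follow the RELION
naming convention; unknown columns are carried through verbatim so that a
read/write cycle never destroys refinement metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

from .errors import EmptyInputError, MissingColumnError, StarParseError

__all__ = ["ParticleRecord", "ParticleSet", "read_particles", "write_particles"]

# RELION column names for the fields the curation math needs.
COL_MICROGRAPH = "rlnMicrographName"
COL_TUBE = "rlnHelicalTubeID"
COL_X = "rlnCoordinateX"
COL_Y = "rlnCoordinateY"
COL_ROT = "rlnAngleRot"
COL_TILT = "rlnAngleTilt"
COL_PSI = "rlnAnglePsi"
COL_OX_ANG = "rlnOriginXAngst"
COL_OY_ANG = "rlnOriginYAngst"
COL_OX_PIX = "rlnOriginX"
COL_OY_PIX = "rlnOriginY"
COL_DU = "rlnDefocusU"
COL_DV = "rlnDefocusV"
COL_DANG = "rlnDefocusAngle"
COL_PIXSIZE = "rlnImagePixelSize"

REQUIRED_COLUMNS = (COL_MICROGRAPH, COL_TUBE, COL_X, COL_Y, COL_PSI, COL_DU)

_KNOWN_COLUMNS = {
    COL_MICROGRAPH, COL_TUBE, COL_X, COL_Y, COL_ROT, COL_TILT, COL_PSI,
    COL_OX_ANG, COL_OY_ANG, COL_OX_PIX, COL_OY_PIX,
    COL_DU, COL_DV, COL_DANG, COL_PIXSIZE,
}


@dataclass
class ParticleRecord:
    """One extracted helical segment.

    Origins follow the subtractive convention and are stored in Å
    regardless of the dialect of the source table.
    """

    micrograph_id: str
    tube_id: int
    coord_x: float
    coord_y: float
    psi: float
    tilt: float = 90.0
    rot: float = 0.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    defocus_u: float = 0.0
    defocus_v: float = 0.0
    defocus_angle: float = 0.0
    pixel_size: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def copy(self, **changes) -> "ParticleRecord":
        rec = replace(self, **changes)
        rec.extra = dict(self.extra)
        return rec


@dataclass
class ParticleSet:
    records: list[ParticleRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _parse_float(token: str, column: str, row: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise StarParseError(
            f"malformed numeric value {token!r} in column {column}", row=row
        ) from None
    if not math.isfinite(value):
        raise StarParseError(
            f"non-finite value {token!r} in column {column}", row=row
        )
    return value


def _parse_int(token: str, column: str, row: int) -> int:
    try:
        return int(float(token))
    except ValueError:
        raise StarParseError(
            f"malformed integer value {token!r} in column {column}", row=row
        ) from None


def _scan_loop(text: str) -> tuple[list[str], list[list[str]]]:
    """Return (column names, data rows) of the first loop in a STAR text."""
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n and lines[i].strip() != "loop_":
        i += 1
    if i == n:
        raise StarParseError("no loop_ block found")
    i += 1
    columns: list[str] = []
    while i < n:
        stripped = lines[i].strip()
        if stripped.startswith("_"):
            columns.append(stripped.split()[0].lstrip("_"))
            i += 1
        else:
            break
    if not columns:
        raise StarParseError("loop_ block declares no columns")
    rows: list[list[str]] = []
    while i < n:
        stripped = lines[i].strip()
        if not stripped or stripped.startswith(("data_", "loop_", "#")):
            break
        tokens = stripped.split()
        if len(tokens) != len(columns):
            raise StarParseError(
                f"expected {len(columns)} fields, found {len(tokens)}",
                row=len(rows),
            )
        rows.append(tokens)
        i += 1
    return columns, rows


def read_particles(
    path: str | Path, default_pixel_size: float | None = None
) -> ParticleSet:
    """Parse a particle table into a :class:`ParticleSet`.

    Unknown columns are preserved verbatim in each record's ``extra`` dict.
    Pixel-valued origin shifts are converted to Å at parse time; which
    dialect was seen is recorded in ``provenance['origin_dialect']``.
    """
    path = Path(path)
    columns, rows = _scan_loop(path.read_text())
    colset = set(columns)
    for col in REQUIRED_COLUMNS:
        if col not in colset:
            raise MissingColumnError(col)

    origin_dialect = "none"
    if COL_OX_ANG in colset or COL_OY_ANG in colset:
        origin_dialect = "angstrom"
    elif COL_OX_PIX in colset or COL_OY_PIX in colset:
        origin_dialect = "pixel"

    idx = {c: k for k, c in enumerate(columns)}
    extra_cols = [c for c in columns if c not in _KNOWN_COLUMNS]

    records: list[ParticleRecord] = []
    for r, tokens in enumerate(rows):
        def fget(col: str, default: float | None = None) -> float | None:
            if col in idx:
                return _parse_float(tokens[idx[col]], col, r)
            return default

        pixel_size = fget(COL_PIXSIZE, default_pixel_size)
        du = fget(COL_DU)
        dv = fget(COL_DV, du)
        if origin_dialect == "pixel":
            if pixel_size is None:
                raise StarParseError(
                    "pixel-valued origins require a pixel size "
                    f"(column {COL_PIXSIZE} or default_pixel_size)", row=r
                )
            origin_x = fget(COL_OX_PIX, 0.0) * pixel_size
            origin_y = fget(COL_OY_PIX, 0.0) * pixel_size
        else:
            origin_x = fget(COL_OX_ANG, 0.0)
            origin_y = fget(COL_OY_ANG, 0.0)

        records.append(ParticleRecord(
            micrograph_id=tokens[idx[COL_MICROGRAPH]],
            tube_id=_parse_int(tokens[idx[COL_TUBE]], COL_TUBE, r),
            coord_x=fget(COL_X),
            coord_y=fget(COL_Y),
            psi=fget(COL_PSI),
            tilt=fget(COL_TILT, 90.0),
            rot=fget(COL_ROT, 0.0),
            origin_x=origin_x,
            origin_y=origin_y,
            defocus_u=du,
            defocus_v=dv,
            defocus_angle=fget(COL_DANG, 0.0),
            pixel_size=pixel_size,
            extra={c: tokens[idx[c]] for c in extra_cols},
        ))

    return ParticleSet(
        records=records,
        provenance={"source": str(path), "origin_dialect": origin_dialect},
    )


def _format_row(rec: ParticleRecord, extra_cols: list[str],
                with_pixel_size: bool) -> str:
    fields = [
        rec.micrograph_id,
        str(rec.tube_id),
        f"{rec.coord_x:.6f}",
        f"{rec.coord_y:.6f}",
        f"{rec.rot:.6f}",
        f"{rec.tilt:.6f}",
        f"{rec.psi:.6f}",
        f"{rec.origin_x:.6f}",
        f"{rec.origin_y:.6f}",
        f"{rec.defocus_u:.6f}",
        f"{rec.defocus_v:.6f}",
        f"{rec.defocus_angle:.6f}",
    ]
    if with_pixel_size:
        fields.append(f"{rec.pixel_size:.6f}")
    fields.extend(rec.extra.get(c, "''") for c in extra_cols)
    return " ".join(fields)


def write_particles(particle_set: ParticleSet, path: str | Path) -> None:
    """Write a particle table; origins are always emitted in Å.

    Column order is deterministic: the canonical columns first, then any
    passthrough columns in first-seen order.
    """
    if not particle_set.records:
        raise EmptyInputError("refusing to write an empty particle set")
    path = Path(path)

    extra_cols: list[str] = []
    for rec in particle_set.records:
        for c in rec.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    with_pixel_size = all(
        rec.pixel_size is not None for rec in particle_set.records
    )

    columns = [
        COL_MICROGRAPH, COL_TUBE, COL_X, COL_Y,
        COL_ROT, COL_TILT, COL_PSI,
        COL_OX_ANG, COL_OY_ANG,
        COL_DU, COL_DV, COL_DANG,
    ]
    if with_pixel_size:
        columns.append(COL_PIXSIZE)
    columns.extend(extra_cols)

    lines = ["data_particles", "", "loop_"]
    lines.extend(f"_{c} #{k + 1}" for k, c in enumerate(columns))
    lines.extend(
        _format_row(rec, extra_cols, with_pixel_size)
        for rec in particle_set.records
    )
    path.write_text("\n".join(lines) + "\n")
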