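"""Atomic model reading (PDB and mmCIF) backed by biotite.

Altloc resolution keeps the highest-occupancy conformer.  Format is
auto-detected from the file suffix, falling back to content sniffing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure.io.pdb as pdb
import biotite.structure.io.pdbx as pdbx

from ..errors import FormatError
from .types import Atom, Structure

__all__ = ["read_structure"]

_EXTRA_FIELDS = ["b_factor", "occupancy"]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix in {".cif", ".mmcif", ".pdbx"}:
        return "cif"
    head = path.read_text(errors="replace")[:4000]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "cif"
    return "pdb"


def _load_atom_array(path: Path, fmt: str):
    if fmt == "pdb":
        f = pdb.PDBFile.read(str(path))
        return pdb.get_structure(
            f, model=1, altloc="occupancy", extra_fields=_EXTRA_FIELDS
        )
    f = pdbx.CIFFile.read(str(path))
    return pdbx.get_structure(
        f, model=1, altloc="occupancy", extra_fields=_EXTRA_FIELDS
    )


def read_structure(path) -> Structure:
    """Parse all ATOM/HETATM records of the first model into a Structure."""
    path = Path(path)
    fmt = _detect_format(path)
    try:
        arr = _load_atom_array(path, fmt)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    atoms = []
    occ = getattr(arr, "occupancy", None)
    bfac = getattr(arr, "b_factor", None)
    for i in range(arr.array_length()):
        atoms.append(Atom(
            element=str(arr.element[i]).capitalize(),
            atom_name=str(arr.atom_name[i]),
            residue_name=str(arr.res_name[i]),
            residue_number=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]),
            position=np.asarray(arr.coord[i], dtype=float),
            b_factor=float(bfac[i]) if bfac is not None else 0.0,
            occupancy=float(occ[i]) if occ is not None else 1.0,
        ))
    return Structure(atoms=atoms, source=f"{path}:{fmt}")
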