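"""Headline comparisons between deposited filament models.

These helpers wrap the struct_metrics primitives into the specific
measurements quoted for the deposited pyrenyl-filament models.  They
need the coordinate files (PDB or mmCIF) on disk; nothing here downloads
anything.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import SelectionError
from .struct_metrics import (
    Selector,
    Structure,
    min_group_distance,
    read_structure,
    rmsd_selection,
)

__all__ = [
    "interior_chain",
    "calpha_rmsd_between_models",
    "bfactor_percent_diff_373_375",
    "k113_to_cterm_distance",
]


def interior_chain(structure: Structure) -> str:
    """Chain whose Cα centroid lies closest to the assembly centroid.

    In a multi-subunit filament model this picks the central subunit, the
    one with both long-pitch neighbors present.
    """
    cas = [a for a in structure.atoms if a.atom_name == "CA"]
    if not cas:
        raise SelectionError("structure has no CA atoms")
    overall = np.mean([a.position for a in cas], axis=0)
    chains: dict[str, list[np.ndarray]] = {}
    for a in cas:
        chains.setdefault(a.chain_id, []).append(a.position)
    return min(
        chains,
        key=lambda c: float(
            np.linalg.norm(np.mean(chains[c], axis=0) - overall)
        ),
    )


def calpha_rmsd_between_models(path_a: str | Path,
                               path_b: str | Path) -> float:
    """Cα RMSD over all matched chains after least-squares superposition."""
    a = read_structure(path_a)
    b = read_structure(path_b)
    return rmsd_selection(a, b, Selector(atom_names=frozenset({"CA"})),
                          superpose=True)


def bfactor_percent_diff_373_375(path_a: str | Path,
                                 path_b: str | Path) -> float:
    """Percent mean-B difference over residues 373-375, interior subunit.

    Positive when the first model's B-factors are higher.
    """
    a = read_structure(path_a)
    b = read_structure(path_b)

    def mean_b(s: Structure) -> float:
        chain = interior_chain(s)
        sel = Selector(chains=frozenset({chain}),
                       residue_ranges=((373, 375),))
        values = [at.b_factor for at in s.atoms if sel.matches(at)]
        if not values:
            raise SelectionError("residues 373-375 not found")
        return float(np.mean(values))

    ba, bb = mean_b(a), mean_b(b)
    return 100.0 * (ba - bb) / bb


def k113_to_cterm_distance(path: str | Path) -> float:
    """Min distance, K113 side-chain amine N to C-terminal carboxyl O.

    Measured within the interior subunit of the model.
    """
    s = read_structure(path)
    chain = interior_chain(s)
    nz = Selector(chains=frozenset({chain}),
                  residue_ranges=((113, 113),),
                  atom_names=frozenset({"NZ"}))
    carboxyl = Selector(chains=frozenset({chain}),
                        residue_ranges=((375, 375),),
                        atom_names=frozenset({"O", "OXT"}))
    distance, _ = min_group_distance(s, nz, carboxyl)
    return distance
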