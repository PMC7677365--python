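"""Domain types for atomic-model metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Atom:
    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray  # (3,) Å
    b_factor: float = 0.0
    occupancy: float = 1.0

    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


#: backbone heavy-atom names; OXT belongs to the C-terminal carboxyl group
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Structure:
    atoms: list[Atom]
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(-1, 3)

    def subset(self, indices) -> "Structure":
        return Structure([self.atoms[i] for i in indices], self.source)


@dataclass
class Superposition:
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def transform(self, structure: Structure) -> Structure:
        moved = [
            Atom(a.element, a.atom_name, a.residue_name, a.residue_number,
                 a.chain_id, self.apply(a.position.reshape(1, 3))[0],
                 a.b_factor, a.occupancy)
            for a in structure.atoms
        ]
        return Structure(moved, structure.source)


@dataclass
class Clash:
    atom_a: Atom
    atom_b: Atom
    distance: float
    overlap: float  # (vdW_a + vdW_b) - distance


@dataclass
class ClashReport:
    clashes: list[Clash]
    threshold: float

    def __len__(self) -> int:
        return len(self.clashes)

    def pair_labels(self) -> list[tuple[str, str]]:
        def label(a: Atom) -> str:
            return f"{a.chain_id}/{a.residue_name}{a.residue_number}/{a.atom_name}"
        return [(label(c.atom_a), label(c.atom_b)) for c in self.clashes]
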