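"""Atom selections.

A :class:`Selector` can be built directly or parsed from a small text
expression of AND-joined clauses, e.g.::

    chain A and resi 373-375 and sidechain
    name NZ
    resn PYN
    resi 113 and name NZ+NZ2

Clauses: ``chain <ids>``, ``resi <ranges>``, ``name <names>``,
``resn <names>``, ``sidechain``, ``backbone``.  Lists accept ``+`` or
``,`` separators; residue ranges use ``a-b``.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import SelectionError
from .types import BACKBONE_NAMES, Atom, Structure

__all__ = ["Selector", "parse_selection"]


@dataclass
class Selector:
    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None
    residue_names: frozenset[str] | None = None
    sidechain: bool = False
    backbone: bool = False

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.residue_number <= hi
            for lo, hi in self.residue_ranges
        ):
            return False
        if (self.atom_names is not None
                and atom.atom_name not in self.atom_names):
            return False
        if (self.residue_names is not None
                and atom.residue_name not in self.residue_names):
            return False
        name = atom.atom_name
        if self.sidechain and (name in BACKBONE_NAMES
                               or atom.is_hydrogen()):
            return False
        if self.backbone and name not in BACKBONE_NAMES:
            return False
        return True

    def indices(self, structure: Structure) -> list[int]:
        return [i for i, a in enumerate(structure.atoms)
                if self.matches(a)]

    def apply(self, structure: Structure) -> Structure:
        return structure.subset(self.indices(structure))


def _split_list(text: str) -> list[str]:
    return [t for t in text.replace("+", ",").split(",") if t]


def parse_selection(expression: str) -> Selector:
    """Parse an AND-joined selection expression."""
    sel = Selector()
    for clause in expression.split(" and "):
        tokens = clause.strip().split(None, 1)
        if not tokens:
            continue
        keyword = tokens[0].lower()
        arg = tokens[1].strip() if len(tokens) > 1 else ""
        if keyword == "chain":
            sel.chains = frozenset(_split_list(arg))
        elif keyword == "resi":
            ranges = []
            for item in _split_list(arg):
                if "-" in item[1:]:
                    lo, hi = item.rsplit("-", 1)
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(item), int(item)))
            sel.residue_ranges = tuple(ranges)
        elif keyword == "name":
            sel.atom_names = frozenset(_split_list(arg))
        elif keyword == "resn":
            sel.residue_names = frozenset(_split_list(arg))
        elif keyword == "sidechain":
            sel.sidechain = True
        elif keyword == "backbone":
            sel.backbone = True
        else:
            raise SelectionError(f"unknown selection keyword {keyword!r}")
    return sel
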