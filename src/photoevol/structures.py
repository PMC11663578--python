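"""Macromolecular structure data model and PDB parsing (via gemmi).

Only what the contact analysis needs is retained: chains of residues
with numbered, element-assigned atoms and a polymer/hetero flag.
Alternate locations are collapsed to the highest-occupancy conformer
(ties keep the first encountered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np


class StructureError(ValueError):
    """Raised when no atoms can be parsed or coordinates are bad."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    hetero: bool
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[Residue]]

    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues() if not r.hetero]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.hetero]


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    source: str | Path, structure_id: str | None = None, drop_hydrogens: bool = False
) -> StructureModel:
    """Parse PDB-format text (path or literal string) into a StructureModel.

    HETATM residues are flagged hetero.  Raises :class:`StructureError`
    when no atoms are found or any coordinate is non-finite.
    """
    text = None
    p = Path(str(source))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(source)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    chains: dict[str, list[Residue]] = {}
    seen: set[tuple[str, int, str]] = set()
    n_atoms = 0
    for model in st:
        for chain in model:
            for res in chain:
                hetero = res.het_flag == "H"
                key = (chain.name, res.seqid.num, res.seqid.icode.strip())
                if key in seen:
                    raise StructureError(f"duplicate residue {key}")
                seen.add(key)
                atoms = []
                for atom in _collapse_altlocs(res):
                    element = atom.element.name.upper()
                    if drop_hydrogens and element in ("H", "D"):
                        continue
                    pos = atom.pos
                    if not all(map(math.isfinite, (pos.x, pos.y, pos.z))):
                        raise StructureError(f"non-finite coordinates at {key}")
                    atoms.append(Atom(atom.name, element, pos.x, pos.y, pos.z))
                n_atoms += len(atoms)
                chains.setdefault(chain.name, []).append(
                    Residue(chain.name, res.seqid.num, key[2], res.name, hetero, atoms)
                )
        break  # first model only
    if n_atoms == 0:
        raise StructureError("no atoms parsed from input")
    return StructureModel(structure_id or st.name or "structure", chains)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


def chain_sequence(structure: StructureModel, chain: str) -> tuple[str, list[tuple[str, int, str]]]:
    """One-letter sequence of a chain's polymer residues plus their keys."""
    if chain not in structure.chains:
        raise KeyError(chain)
    seq, keys = [], []
    for res in structure.chains[chain]:
        if res.hetero:
            continue
        seq.append(THREE_TO_ONE.get(res.name, "X"))
        keys.append(res.key)
    return "".join(seq), keys
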