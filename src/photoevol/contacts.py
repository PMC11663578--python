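"""Structure-derived residue categories and interface-effect classification.

Cofactor-binding residues: polymer residues with at least one heavy atom
strictly closer than the cutoff (default 4.0 A) to any atom of a
selected pigment/cofactor.  Interface residues: the symmetric analogue
between two protein chains.  Neighbor searches use a k-d tree and are
exactly equivalent to the all-pairs scan.

Interface-effect classification takes externally computed ddG values
(kcal/mol) and applies the magnitude rule |ddG| >= threshold (default
0.5): negative values stabilize the interface, positive destabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial import cKDTree

from .structures import Residue, StructureModel


@dataclass
class ContactSet:
    structure_id: str
    category: str  # "cofactor-binding" | "interface"
    members: set[tuple[str, int, str]]
    cutoff: float
    chain_pair: tuple[str, str] | None = None

    def __contains__(self, key) -> bool:
        return key in self.members


def _residue_heavy_coords(
    residues: list[Residue],
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    coords, owners = [], []
    for res in residues:
        for atom in res.heavy_atoms():
            coords.append(atom.xyz)
            owners.append(res.key)
    return np.array(coords).reshape(-1, 3), owners


def cofactor_binding_residues(
    structure: StructureModel,
    cofactor_names: list[str] | None = None,
    cutoff: float = 4.0,
) -> ContactSet:
    """Polymer residues with a heavy atom strictly within ``cutoff`` of a cofactor.

    ``cofactor_names`` restricts the cofactor selection to those hetero
    residue names; by default every hetero residue counts as a cofactor.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cofactors = [
        r
        for r in structure.hetero_residues()
        if cofactor_names is None or r.name in cofactor_names
    ]
    if not cofactors:
        warnings.warn("cofactor selector matched nothing; empty contact set")
        return ContactSet(structure.id, "cofactor-binding", set(), cutoff)
    lig_xyz, _ = _residue_heavy_coords(cofactors)
    poly_xyz, owners = _residue_heavy_coords(structure.polymer_residues())
    members: set[tuple[str, int, str]] = set()
    if len(lig_xyz) and len(poly_xyz):
        tree = cKDTree(lig_xyz)
        dists, _ = tree.query(poly_xyz, k=1)
        for d, owner in zip(dists, owners):
            if d < cutoff:  # strict inequality
                members.add(owner)
    return ContactSet(structure.id, "cofactor-binding", members, cutoff)


def interface_residues(
    structure: StructureModel,
    chain_pairs: list[tuple[str, str]],
    cutoff: float = 4.0,
) -> dict[tuple[str, str], ContactSet]:
    """Residues of either chain with a heavy atom within ``cutoff`` of the partner."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out: dict[tuple[str, str], ContactSet] = {}
    for a, b in chain_pairs:
        for c in (a, b):
            if c not in structure.chains:
                raise KeyError(f"chain {c!r} not in structure")
        res_a = [r for r in structure.chains[a] if not r.hetero]
        res_b = [r for r in structure.chains[b] if not r.hetero]
        xyz_a, own_a = _residue_heavy_coords(res_a)
        xyz_b, own_b = _residue_heavy_coords(res_b)
        members: set[tuple[str, int, str]] = set()
        if len(xyz_a) and len(xyz_b):
            tree = cKDTree(xyz_b)
            d_a, _ = tree.query(xyz_a, k=1)
            members |= {o for d, o in zip(d_a, own_a) if d < cutoff}
            tree_a = cKDTree(xyz_a)
            d_b, _ = tree_a.query(xyz_b, k=1)
            members |= {o for d, o in zip(d_b, own_b) if d < cutoff}
        out[(a, b)] = ContactSet(structure.id, "interface", members, cutoff, (a, b))
    return out


@dataclass
class ResidueMap:
    """Structure-residue -> 1-based alignment-column map for one gene."""

    chain: str
    mapping: dict[tuple[str, int, str], int]
    identity: float
    coverage: float
    low_identity: bool
    mismatches: list[tuple[tuple[str, int, str], str, str]] = field(default_factory=list)


def map_structure_to_alignment(
    chain_seq: str,
    residue_keys: list[tuple[str, int, str]],
    reference_row: str,
    chain: str = "",
    min_identity: float = 0.30,
) -> ResidueMap:
    """Global pairwise alignment of a chain sequence onto a gapped reference row.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1.  The
    reference row keeps its alignment gaps, so the induced map goes
    straight to 1-based alignment columns; reference-gap columns are
    unmapped.  Falls below ``min_identity`` -> the map carries a
    low-identity warning flag.
    """
    if len(chain_seq) != len(residue_keys):
        raise ValueError("chain sequence and residue keys differ in length")
    ref_ungapped = []
    ref_columns = []
    for col, ch in enumerate(reference_row, start=1):
        if ch not in "-.?":
            ref_ungapped.append(ch.upper())
            ref_columns.append(col)
    ref = "".join(ref_ungapped)
    if not ref or not chain_seq:
        raise ValueError("empty sequence in structure-to-alignment mapping")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(chain_seq, ref)[0]

    mapping: dict[tuple[str, int, str], int] = {}
    mismatches = []
    matches = aligned_len = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            aligned_len += 1
            mapping[residue_keys[qi]] = ref_columns[ti]
            if chain_seq[qi].upper() == ref[ti]:
                matches += 1
            else:
                mismatches.append((residue_keys[qi], chain_seq[qi], ref[ti]))
    identity = matches / aligned_len if aligned_len else 0.0
    coverage = aligned_len / len(chain_seq)
    return ResidueMap(
        chain=chain,
        mapping=mapping,
        identity=identity,
        coverage=coverage,
        low_identity=identity < min_identity,
        mismatches=mismatches,
    )


# -- ddG classification ---------------------------------------------------

EFFECT_CLASSES = ("stabilizing", "destabilizing", "negligible")


def classify_interface_effect(
    table: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify per-substitution interface ddG values.

    ``table`` needs a ``ddg_kcal_mol`` column.  ddG <= -threshold ->
    stabilizing, ddG >= +threshold -> destabilizing, else negligible
    (the magnitude rule is inclusive at the threshold).  Non-finite
    values are rejected into a ``rejected`` flag column.  Returns the
    annotated table and the per-class counts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = table.copy()
    ddg = pd.to_numeric(out["ddg_kcal_mol"], errors="coerce")
    finite = np.isfinite(ddg)
    cls = np.full(len(out), "negligible", dtype=object)
    cls[finite & (ddg <= -threshold)] = "stabilizing"
    cls[finite & (ddg >= threshold)] = "destabilizing"
    cls[~finite] = "rejected"
    out["classification"] = cls
    out["rejected"] = ~finite
    counts = (
        out.loc[finite, "classification"].value_counts().reindex(EFFECT_CLASSES, fill_value=0)
    )
    return out, counts


def load_packaged_ddg_table() -> pd.DataFrame:
    """The shipped per-substitution interface ddG table (TSV fixture)."""
    ref = resources.files("photoevol.data") / "table1_ddg.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
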