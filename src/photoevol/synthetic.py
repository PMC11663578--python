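"""Synthetic study inputs: trees, alignments with known histories,
injected convergent substitutions, and toy structures.

This module stands in for the real dataset (hundreds of plastid genomes,
cryo-EM photosystem structures): it produces every input the pipeline
consumes, with recorded ground truth, so the full analysis runs and can
be validated end to end with no downloads.  Everything is a pure
function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import SubstitutionModel
from .seqio import Alignment
from .substmap import SubstitutionEvent
from .trees import PhyloTree, TreeNode


class SimulationSizeError(RuntimeError):
    """The requested simulation exceeds the configured work budget."""


DEFAULT_BUDGET = 500_000_000  # nodes x sites upper bound across one call


def generate_random_tree(
    n_leaves: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    height: Optional[float] = None,
) -> PhyloTree:
    """Rooted binary Yule (pure-birth) tree with exponential waiting times.

    Two lineages leave the root at time 0; each split picks a uniform
    lineage after an Exp(n * birth_rate) wait.  Terminal branches extend
    one further exponential wait past the last split.  If ``height`` is
    given, all branch lengths are rescaled so the root-to-tip distance
    equals it.
    """
    if n_leaves < 2:
        raise ValueError("a Yule tree needs at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode("", None)
    active: list[tuple[TreeNode, float]] = [
        (root.add_child(TreeNode("", 0.0)), 0.0),
        (root.add_child(TreeNode("", 0.0)), 0.0),
    ]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, born = active.pop(i)
        node.length = t - born
        active.append((node.add_child(TreeNode("", 0.0)), t))
        active.append((node.add_child(TreeNode("", 0.0)), t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for j, (node, born) in enumerate(active):
        node.length = t - born
    # deterministic leaf naming in left-to-right tree order
    counter = 1
    stack = [root]
    order: list[TreeNode] = []
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(reversed(n.children))
    for n in order:
        if not n.children:
            n.name = f"t{counter}"
            counter += 1
    if height is not None:
        if height <= 0:
            raise ValueError("height must be positive")
        factor = height / t
        for n in order:
            if n.length is not None:
                n.length *= factor
    return PhyloTree(root)


@dataclass
class SimulationResult:
    alignment: Alignment
    node_sequences: dict[str, str]  # internal nodes, root included
    true_events: list[SubstitutionEvent]
    site_categories: np.ndarray


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    root_mode: str = "stationary",
    seed: int | np.random.Generator = 0,
    gene: str = "gene",
    budget: int = DEFAULT_BUDGET,
) -> SimulationResult:
    """Evolve sequences down the tree; record the realized history.

    ``root_mode`` is either ``"stationary"`` (root drawn from pi) or a
    concrete root sequence.  Each site draws its rate category once from
    the mixture weights.  True events are endpoint comparisons per
    branch (multiple hits on one branch collapse), i.e. exactly what any
    parent/child reconstruction could recover.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = list(tree.postorder())
    if len(nodes) * n_sites > budget:
        raise SimulationSizeError(
            f"{len(nodes)} nodes x {n_sites} sites exceeds budget {budget}"
        )
    k, C = model.k, model.n_categories
    idx = {s: i for i, s in enumerate(model.states)}
    cats = rng.choice(C, size=n_sites, p=model.weights)

    if root_mode == "stationary":
        root_states = rng.choice(k, size=n_sites, p=model.pi)
    else:
        if len(root_mode) != n_sites:
            raise ValueError("root sequence length does not match n_sites")
        try:
            root_states = np.array([idx[c] for c in root_mode.upper()])
        except KeyError as exc:
            raise ValueError(f"root sequence has non-concrete state {exc}") from None

    states_of: dict[str, np.ndarray] = {tree.root.name: root_states}
    events: list[SubstitutionEvent] = []
    for node in tree.preorder():
        if node.is_root:
            continue
        parent_states = states_of[node.parent.name]
        P = model.transition_matrices(node.length)  # (C, k, k)
        probs = P[cats, parent_states, :]  # (n_sites, k)
        u = rng.random(n_sites)
        child_states = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        child_states = np.minimum(child_states, k - 1)
        states_of[node.name] = child_states
        changed = np.nonzero(child_states != parent_states)[0]
        for s in changed:
            events.append(
                SubstitutionEvent(
                    gene,
                    int(s) + 1,
                    node.name,
                    model.states[parent_states[s]],
                    model.states[child_states[s]],
                    layer="amino-acid" if k == 20 else "nucleotide",
                )
            )

    state_bytes = np.frombuffer(model.states.encode("ascii"), dtype=np.uint8)
    to_seq = lambda arr: state_bytes[arr].tobytes().decode("ascii")
    leaf_names = set(tree.leaf_labels)
    alignment = Alignment(
        {name: to_seq(states_of[name]) for name in tree.leaf_labels},
        alphabet="amino-acid" if k == 20 else "nucleotide",
    )
    node_sequences = {
        name: to_seq(arr) for name, arr in states_of.items() if name not in leaf_names
    }
    return SimulationResult(alignment, node_sequences, events, cats)


def inject_convergent_events(
    aln: Alignment,
    tree: PhyloTree,
    site: int,
    x: str,
    y: str,
    branches: Sequence[str],
    model: SubstitutionModel,
    seed: int | np.random.Generator = 0,
) -> Alignment:
    """Overwrite one column with a convergent X->Y scenario.

    The column (1-based ``site``) is re-simulated with the root fixed at
    state X so the background lineages carry X (re-drawn, seeded, until
    at least ``min_background_frac`` of the non-injected leaves do — a
    lineage-wide drift away from X would otherwise erase the convergent
    signal); then every leaf below each chosen branch is set to Y.
    Branches must be pairwise non-nested so the injected events are
    independent.
    """
    if x == y:
        raise ValueError("injected states must differ")
    branch_nodes = [tree.node(b) for b in branches]
    for i, a in enumerate(branch_nodes):
        for b in branch_nodes[i + 1 :]:
            if tree.in_clade(a, b) or tree.in_clade(b, a):
                raise ValueError(f"nested injection branches: {a.name}, {b.name}")
    if branch_nodes:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        injected_leaves = set().union(
            *(tree.descendant_leaves(n) for n in branch_nodes)
        )
        background = [l for l in tree.leaf_labels if l not in injected_leaves]
        min_background_frac = 0.8
        column = None
        for _ in range(200):
            column_sim = simulate_alignment(tree, model, 1, root_mode=x, seed=rng)
            cand = {rid: seq[0] for rid, seq in column_sim.alignment.records.items()}
            frac = (
                sum(1 for l in background if cand[l] == x) / len(background)
                if background
                else 1.0
            )
            if frac >= min_background_frac:
                column = cand
                break
        if column is None:  # pathological drift: fall back to a clean background
            column = {l: x for l in tree.leaf_labels}
        for node in branch_nodes:
            for leaf in tree.descendant_leaves(node):
                column[leaf] = y
    else:
        column = {rid: seq[site - 1] for rid, seq in aln.records.items()}
    records = {
        rid: seq[: site - 1] + column[rid] + seq[site:]
        for rid, seq in aln.records.items()
    }
    return Alignment(records, aln.alphabet)


# -- toy structures ------------------------------------------------------

@dataclass
class ToyStructureSpec:
    """Two poly-alanine chains plus a ligand at controlled distances.

    Chain A runs along x with one CA per ``residue_spacing`` angstroms;
    chain B is parallel at ``chain_separation`` in y.  The ligand sits at
    ``ligand_distance`` (in y, negative side) from chain A residue
    ``ligand_anchor``'s CA.  ``contact_pair=(resA, resB, d)`` pulls chain
    B residue resB to exactly d angstroms from chain A residue resA.
    ``hydrogen_near_ligand`` optionally adds a hydrogen at that distance
    from the ligand to exercise the heavy-atom rule.
    """

    residues_per_chain: int = 5
    residue_spacing: float = 5.0
    chain_separation: float = 50.0
    ligand_distance: float = 3.9
    ligand_anchor: int = 1
    ligand_name: str = "LIG"
    contact_pair: Optional[tuple[int, int, float]] = None
    hydrogen_near_ligand: Optional[float] = None


def _pdb_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    element: str,
    hetero: bool = False,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    aname = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {aname:<4s} {resname:>3s} {chain:1s}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def generate_toy_structure(spec: ToyStructureSpec) -> str:
    """Emit fixed-width PDB text realizing the requested distances exactly."""
    if spec.residues_per_chain < 1:
        raise ValueError("need at least one residue per chain")
    if spec.ligand_distance <= 0 or (
        spec.contact_pair is not None and spec.contact_pair[2] <= 0
    ):
        raise ValueError("requested distances must be positive")
    lines = []
    serial = 1
    coords: dict[tuple[str, int], tuple[float, float, float]] = {}
    anchor = ((spec.ligand_anchor - 1) * spec.residue_spacing, 0.0, 0.0)
    ligand_pos = (anchor[0], anchor[1] - spec.ligand_distance, anchor[2])
    for chain, y0 in (("A", 0.0), ("B", spec.chain_separation)):
        for r in range(1, spec.residues_per_chain + 1):
            x = (r - 1) * spec.residue_spacing
            pos = (x, y0, 0.0)
            if (
                chain == "B"
                and spec.contact_pair is not None
                and r == spec.contact_pair[1]
            ):
                ra, _, d = spec.contact_pair
                ax = (ra - 1) * spec.residue_spacing
                pos = (ax, d, 0.0)  # exactly d from chain A residue ra's CA
            coords[(chain, r)] = pos
            lines.append(_pdb_atom(serial, "N", "ALA", chain, r, (pos[0] - 0.8, pos[1], 0.6), "N"))
            serial += 1
            lines.append(_pdb_atom(serial, "CA", "ALA", chain, r, pos, "C"))
            serial += 1
        if chain == "A" and spec.hydrogen_near_ligand is not None:
            # extra residue whose hydrogen sits near the ligand while its
            # heavy atom stays far: exercises the heavy-atom-only rule
            r = spec.residues_per_chain + 1
            hx = (
                ligand_pos[0] + spec.hydrogen_near_ligand,
                ligand_pos[1],
                ligand_pos[2],
            )
            lines.append(_pdb_atom(serial, "CA", "GLY", chain, r, (hx[0] + 50.0, hx[1], hx[2]), "C"))
            serial += 1
            lines.append(_pdb_atom(serial, "HA", "GLY", chain, r, hx, "H"))
            serial += 1
    lines.append(
        _pdb_atom(serial, "C1", spec.ligand_name, "L", 1, ligand_pos, "C", hetero=True)
    )
    serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
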