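"""Branch-anchored substitution events and per-site/per-protein summaries.

Events are parent->child state changes read off the tree after ancestral
reconstruction: internal nodes carry MAP sequences, leaves carry the
observed alignment rows.  Site numbers are 1-based alignment columns
(post-trim; the trim column map recovers original coordinates).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabets import AA_STATES, NT_STATES
from .seqio import Alignment
from .trees import PhyloTree


@dataclass(frozen=True)
class SubstitutionEvent:
    """One inferred parent->child state change at (gene, site, branch).

    ``branch`` is the child-node name; ``site`` is a 1-based column.
    """

    gene: str
    site: int
    branch: str
    parent_state: str
    child_state: str
    layer: str = "amino-acid"

    def __post_init__(self):
        if self.parent_state == self.child_state:
            raise ValueError("event states must differ")


@dataclass
class SiteSubstitutionMatrix:
    """Per-site k x k count matrix.

    Orientation: columns index the parent residue, rows the child residue,
    so ``matrix[child_index, parent_index]`` counts parent->child changes.
    """

    site: int
    states: str
    matrix: np.ndarray

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def _concrete(ch: str, states: str) -> bool:
    return ch in states


def extract_substitution_events(
    tree: PhyloTree,
    node_sequences: dict[str, str],
    leaf_aln: Alignment,
    gene: str = "gene",
    exclude_clade: str | set[str] | None = None,
    layer: str = "amino-acid",
) -> list[SubstitutionEvent]:
    """Emit one event per (branch, site) where parent and child states differ.

    ``node_sequences`` maps internal-node names to reconstructed sequences;
    leaves take their observed rows from ``leaf_aln``.  Sites where either
    state is a gap or ambiguity code yield no event.  Branches inside (or
    leading into) the excluded clade are skipped entirely.
    """
    states = AA_STATES if layer == "amino-acid" else NT_STATES
    exclude_node = None
    if exclude_clade is not None:
        exclude_node = tree.mrca(
            {exclude_clade} if isinstance(exclude_clade, str) else set(exclude_clade)
        )
    elif tree.outgroup_node is not None:
        exclude_node = tree.outgroup_node

    def seq_of(node) -> str:
        if node.is_leaf:
            try:
                return leaf_aln.records[node.name]
            except KeyError:
                raise KeyError(f"leaf {node.name!r} missing from alignment") from None
        try:
            return node_sequences[node.name]
        except KeyError:
            raise KeyError(f"internal node {node.name!r} has no reconstructed sequence") from None

    n_sites = len(next(iter(leaf_aln.records.values())))
    events: list[SubstitutionEvent] = []
    for node in tree.preorder():
        if node.is_root:
            continue
        if exclude_node is not None and tree.in_clade(node, exclude_node):
            continue
        pseq, cseq = seq_of(node.parent), seq_of(node)
        if len(pseq) != n_sites or len(cseq) != n_sites:
            raise ValueError(f"sequence length mismatch on branch {node.name!r}")
        for s in range(n_sites):
            a, b = pseq[s], cseq[s]
            if a != b and _concrete(a, states) and _concrete(b, states):
                events.append(
                    SubstitutionEvent(gene, s + 1, node.name, a, b, layer)
                )
    return events


def tabulate_site_matrices(
    events: list[SubstitutionEvent],
) -> list[SiteSubstitutionMatrix]:
    """Partition events by site into parent-column/child-row count matrices."""
    if not events:
        return []
    layers = {e.layer for e in events}
    genes = {e.gene for e in events}
    if len(layers) != 1 or len(genes) != 1:
        raise ValueError("events must share one gene and one layer")
    states = AA_STATES if events[0].layer == "amino-acid" else NT_STATES
    idx = {s: i for i, s in enumerate(states)}
    by_site: dict[int, np.ndarray] = defaultdict(
        lambda: np.zeros((len(states), len(states)), dtype=int)
    )
    for e in events:
        by_site[e.site][idx[e.child_state], idx[e.parent_state]] += 1
    return [
        SiteSubstitutionMatrix(site, states, by_site[site])
        for site in sorted(by_site)
    ]


def invariant_sites(aln: Alignment) -> tuple[set[int], set[int], set[int]]:
    """Classify 1-based columns as (invariant, variant, indeterminate).

    Gaps and ambiguity codes are ignored; a column is invariant iff all
    remaining characters are identical.  All-gap/ambiguous columns are
    indeterminate and belong to neither set.
    """
    states = AA_STATES if aln.alphabet == "amino-acid" else NT_STATES
    invariant, variant, indeterminate = set(), set(), set()
    for s in range(aln.n_sites):
        chars = {c for c in aln.column(s) if _concrete(c, states)}
        if not chars:
            indeterminate.add(s + 1)
        elif len(chars) == 1:
            invariant.add(s + 1)
        else:
            variant.add(s + 1)
    return invariant, variant, indeterminate


def protein_substitution_summary(
    events_by_gene: dict[str, list[SubstitutionEvent]],
    protein_lengths: dict[str, int],
    invariant_sets: dict[str, set[int]] | None = None,
) -> pd.DataFrame:
    """One row per gene: totals, substitutions/residue, invariant fraction."""
    rows = []
    for gene, events in events_by_gene.items():
        if gene not in protein_lengths:
            raise KeyError(f"no protein length for gene {gene!r}")
        length = protein_lengths[gene]
        if length <= 0:
            raise ValueError(f"non-positive length for {gene!r}")
        n_inv = len(invariant_sets[gene]) if invariant_sets else None
        rows.append(
            {
                "gene": gene,
                "length": length,
                "n_substitutions": len(events),
                "subs_per_residue": len(events) / length,
                "n_invariant": n_inv,
                "invariant_fraction": (n_inv / length) if n_inv is not None else None,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("n_substitutions", ascending=False).reset_index(drop=True)


def events_to_frame(events: list[SubstitutionEvent]) -> pd.DataFrame:
    """Long-format table: gene, site, branch, parent, child, layer."""
    return pd.DataFrame(
        [
            {
                "gene": e.gene,
                "site": e.site,
                "branch": e.branch,
                "parent": e.parent_state,
                "child": e.child_state,
                "layer": e.layer,
            }
            for e in events
        ],
        columns=["gene", "site", "branch", "parent", "child", "layer"],
    )


def matrices_to_frame(matrices: list[SiteSubstitutionMatrix]) -> pd.DataFrame:
    """Long-format site matrices: site, parent, child, count (nonzero cells)."""
    rows = []
    for m in matrices:
        child_idx, parent_idx = np.nonzero(m.matrix)
        for ci, pi in zip(child_idx, parent_idx):
            rows.append(
                {
                    "site": m.site,
                    "parent": m.states[pi],
                    "child": m.states[ci],
                    "count": int(m.matrix[ci, pi]),
                }
            )
    return pd.DataFrame(rows, columns=["site", "parent", "child", "count"])
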