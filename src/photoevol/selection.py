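"""Counting-based site-wise selection classification from codon data.

Per codon site, nonsynonymous (N) and synonymous (S) event tallies are
read off branch-mapped parent/child codon pairs; multi-nucleotide codon
changes are decomposed by averaging over all orderings of the single
steps, excluding paths through stop codons (the SLAC pathway-averaging
convention).  Each site's observed N is tested against its neutral
nonsynonymous proportion p_N with one-sided binomial tails; classes are
"positive" (excess N), "purifying" (deficit), or "neither".

This is a deliberate, documented counting approximation to likelihood
site-model machinery (per-site ML rate estimation or Bayesian grids);
externally computed site tables with a posterior P(beta > alpha) column
can be supplied instead and are thresholded at 0.9.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import binom, false_discovery_control

from .alphabets import GeneticCode, NT_STATES
from .models import SubstitutionModel
from .seqio import Alignment
from .trees import PhyloTree


def codon_path_counts(
    parent: str, child: str, code: GeneticCode
) -> tuple[float, float] | None:
    """(N, S) counts for one codon change, averaged over mutation orderings.

    Returns None when parent or child is a stop codon or no ordering
    avoids intermediate stops.
    """
    parent, child = parent.upper(), child.upper()
    if parent == child:
        return (0.0, 0.0)
    if code.is_stop(parent) or code.is_stop(child):
        return None
    diff = [i for i in range(3) if parent[i] != child[i]]
    totals = []
    for order in permutations(diff):
        cur = parent
        n = s = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + child[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate_codon(nxt) != code.translate_codon(cur):
                n += 1
            else:
                s += 1
            cur = nxt
        if ok:
            totals.append((n, s))
    if not totals:
        return None
    return (
        float(np.mean([t[0] for t in totals])),
        float(np.mean([t[1] for t in totals])),
    )


def _concrete_codon(codon: str) -> bool:
    return len(codon) == 3 and all(c in NT_STATES for c in codon.upper())


def map_codon_events_ns(
    tree: PhyloTree,
    node_sequences: dict[str, str],
    leaf_aln: Alignment,
    code: GeneticCode | None = None,
    exclude_clade: str | set[str] | None = None,
) -> pd.DataFrame:
    """Per-codon-site (N_obs, S_obs) tallies over all tree branches.

    ``node_sequences`` are reconstructed nucleotide sequences for
    internal nodes; leaves take their rows from the (codon-aligned)
    nucleotide alignment.  Codons containing a gap or ambiguity on
    either side of a branch are skipped; skipped branch-site pairs are
    counted in the ``skipped`` column.
    """
    code = code or GeneticCode(11)
    exclude_node = None
    if exclude_clade is not None:
        exclude_node = tree.mrca(
            {exclude_clade} if isinstance(exclude_clade, str) else set(exclude_clade)
        )
    elif tree.outgroup_node is not None:
        exclude_node = tree.outgroup_node

    length = len(next(iter(leaf_aln.records.values())))
    if length % 3:
        raise ValueError("nucleotide alignment length not a multiple of 3")
    n_codons = length // 3
    N = np.zeros(n_codons)
    S = np.zeros(n_codons)
    skipped = np.zeros(n_codons, dtype=int)

    def seq_of(node) -> str:
        if node.is_leaf:
            return leaf_aln.records[node.name]
        return node_sequences[node.name]

    for node in tree.preorder():
        if node.is_root:
            continue
        if exclude_node is not None and tree.in_clade(node, exclude_node):
            continue
        pseq, cseq = seq_of(node.parent), seq_of(node)
        for site in range(n_codons):
            pc, cc = pseq[site * 3 : site * 3 + 3], cseq[site * 3 : site * 3 + 3]
            if pc == cc:
                continue
            if not (_concrete_codon(pc) and _concrete_codon(cc)):
                skipped[site] += 1
                continue
            counts = codon_path_counts(pc, cc, code)
            if counts is None:
                skipped[site] += 1
                continue
            N[site] += counts[0]
            S[site] += counts[1]
    return pd.DataFrame(
        {"site": np.arange(1, n_codons + 1), "N_obs": N, "S_obs": S, "skipped": skipped}
    )


def neutral_nonsynonymous_proportion(
    codon: str, code: GeneticCode, nt_model: SubstitutionModel | None = None
) -> float:
    """p_N for one parent codon under the nucleotide mutation process.

    Each of the nine single-nucleotide neighbors is weighted by the
    nucleotide model's off-diagonal rate Q[a, b] (uniform rates when no
    model is given); mutations to stop codons are excluded from the
    opportunity set.  p_N is the weighted fraction of the remaining
    opportunities that change the encoded amino acid.
    """
    codon = codon.upper()
    if not _concrete_codon(codon) or code.is_stop(codon):
        raise ValueError(f"need a concrete non-stop codon, got {codon!r}")
    idx = {s: i for i, s in enumerate(NT_STATES)}
    aa = code.translate_codon(codon)
    w_nonsyn = w_total = 0.0
    for pos in range(3):
        for b in NT_STATES:
            if b == codon[pos]:
                continue
            nxt = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(nxt):
                continue
            w = 1.0 if nt_model is None else float(nt_model.Q[idx[codon[pos]], idx[b]])
            w_total += w
            if code.translate_codon(nxt) != aa:
                w_nonsyn += w
    if w_total == 0:
        raise ValueError(f"codon {codon!r} has no non-stop mutational opportunities")
    return w_nonsyn / w_total


def site_neutral_expectation(
    tree: PhyloTree,
    node_sequences: dict[str, str],
    leaf_aln: Alignment,
    code: GeneticCode | None = None,
    nt_model: SubstitutionModel | None = None,
) -> np.ndarray:
    """Per-site p_N averaged over the parent codons of all branch events.

    Sites with no concrete parent codon anywhere fall back to the
    alignment-wide mean p_N.
    """
    code = code or GeneticCode(11)
    length = len(next(iter(leaf_aln.records.values())))
    n_codons = length // 3
    sums = np.zeros(n_codons)
    counts = np.zeros(n_codons)
    for node in tree.preorder():
        if node.is_leaf:
            continue
        seq = node_sequences.get(node.name)
        if seq is None:
            continue
        for site in range(n_codons):
            codon = seq[site * 3 : site * 3 + 3]
            if _concrete_codon(codon) and not code.is_stop(codon):
                sums[site] += neutral_nonsynonymous_proportion(codon, code, nt_model)
                counts[site] += 1
    p = np.full(n_codons, np.nan)
    mask = counts > 0
    p[mask] = sums[mask] / counts[mask]
    if mask.any():
        p[~mask] = p[mask].mean()
    else:
        p[:] = 0.75  # uninformative default: most random codon changes are nonsynonymous
    return p


def classify_site_selection(
    counts: pd.DataFrame,
    p_neutral: np.ndarray,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Binomial-tail selection classes per site.

    For a site with n = N_obs + S_obs scored events, the
    positive-direction p-value is P(X >= N_obs | n, p_N) and the
    purifying-direction p-value is P(X <= N_obs).  Classification uses
    the raw p-values at ``threshold`` plus the rate-direction check
    (beta > alpha for positive, alpha > beta for purifying);
    Benjamini-Hochberg-adjusted columns are reported alongside.
    """
    p_neutral = np.asarray(p_neutral, dtype=float)
    if np.any((p_neutral < 0) | (p_neutral > 1) | ~np.isfinite(p_neutral)):
        raise ValueError("neutral proportions must lie in [0, 1]")
    # parent codons like TGG or ATG have no synonymous single-nucleotide
    # neighbor (p_N exactly 1); keep the binomial well-defined by clipping
    # into the open interval
    eps = 1e-9
    p_neutral = np.clip(p_neutral, eps, 1 - eps)
    out = counts.copy()
    out["p_N"] = p_neutral
    n = out["N_obs"] + out["S_obs"]
    # rate analogues normalized by their neutral opportunity shares
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = out["N_obs"] / (n * out["p_N"])
        alpha = out["S_obs"] / (n * (1 - out["p_N"]))
    out["beta"] = beta.fillna(0.0)
    out["alpha"] = alpha.fillna(0.0)

    n_round = n.round().astype(int)
    x = out["N_obs"].to_numpy()
    p_pos = np.where(
        n_round > 0, binom.sf(np.ceil(x) - 1, n_round, out["p_N"]), np.nan
    )
    p_pur = np.where(n_round > 0, binom.cdf(np.floor(x), n_round, out["p_N"]), np.nan)
    out["p_pos"] = p_pos
    out["p_pur"] = p_pur

    tested = n_round > 0
    for col in ("p_pos", "p_pur"):
        adj = np.full(len(out), np.nan)
        if tested.any():
            adj[tested] = false_discovery_control(out.loc[tested, col], method="bh")
        out[col + "_bh"] = adj

    cls = np.full(len(out), "neither", dtype=object)
    pos = tested & (p_pos <= threshold) & (out["beta"] > out["alpha"])
    pur = tested & (p_pur <= threshold) & (out["alpha"] > out["beta"])
    cls[pos] = "positive"
    cls[pur & ~pos] = "purifying"
    out["classification"] = cls
    return out


def import_external_site_table(
    table: pd.DataFrame, posterior_cutoff: float = 0.9
) -> pd.DataFrame:
    """Adopt an external site table with P(beta > alpha) posteriors.

    Expects columns (site, prob_beta_gt_alpha) and optionally
    prob_alpha_gt_beta; classes follow the standard 0.9 posterior cutoff.
    """
    out = table.copy()
    cls = np.full(len(out), "neither", dtype=object)
    cls[out["prob_beta_gt_alpha"] > posterior_cutoff] = "positive"
    if "prob_alpha_gt_beta" in out:
        pur = (out["prob_alpha_gt_beta"] > posterior_cutoff).to_numpy()
        cls[pur & (cls == "neither")] = "purifying"
    out["classification"] = cls
    return out
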