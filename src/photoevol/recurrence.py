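"""Recurrent-substitution detection and its Monte Carlo significance test.

A recurrent substitution is an X->Y replacement inferred more than once
at one alignment site on different branches.  Whether an observed
multiplicity k is surprising is judged against a simulation null: each
replicate re-simulates the alignment from the fitted model, tree and
root sequence, re-runs ancestral reconstruction on the simulated leaves,
and re-counts recurrences — so reconstruction error is part of the null,
matching how the observed counts were produced.  A key is significant
when no replicate reaches its observed count; the empirical p-value is
reported with the add-one rule p = (m + 1) / (N + 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import TreeLikelihood
from .models import SubstitutionModel
from .substmap import SubstitutionEvent, extract_substitution_events
from .synthetic import SimulationSizeError, simulate_alignment
from .trees import PhyloTree

MATCH_MODES = ("per-site", "per-type-max")


@dataclass
class RecurrenceRecord:
    """Observed multiplicity of an X->Y change at a site plus its null test."""

    gene: str
    site: int
    parent_state: str
    child_state: str
    count: int
    n_sims: int
    exceedance: int  # replicates reaching the observed count
    p_value: float
    significant: bool
    resolution_limited: bool  # (m+1)/(N+1) cannot reach < 0.001 at this N


def count_recurrences(
    events: list[SubstitutionEvent],
) -> dict[tuple[int, str, str], int]:
    """Counts keyed by (site, X, Y); X->Y and Y->X are distinct keys."""
    if events:
        if len({e.gene for e in events}) > 1 or len({e.layer for e in events}) > 1:
            raise ValueError("events must share one gene and one layer")
    return dict(Counter((e.site, e.parent_state, e.child_state) for e in events))


def recurrent_keys(counts: dict[tuple[int, str, str], int]) -> dict[tuple[int, str, str], int]:
    """The subset with count >= 2 (the recurrence definition)."""
    return {k: v for k, v in counts.items() if v >= 2}


def simulate_null_recurrences(
    tree: PhyloTree,
    model: SubstitutionModel,
    root_sequence: str | None,
    n_sites: int,
    n_sims: int,
    seed: int,
    exclude_clade: str | set[str] | None = None,
    true_history_only: bool = False,
    budget: int = 2_000_000_000,
) -> list[dict[tuple[int, str, str], int]]:
    """Per-replicate recurrence-count tables under the model null.

    Each replicate simulates leaves from ``root_sequence`` (or the
    stationary distribution when None), reconstructs ancestral states on
    the simulated alignment, extracts events and counts recurrences.
    ``true_history_only`` skips the reconstruction step and counts the
    simulated history directly — faster, but NOT the faithful null
    (reconstruction error is excluded); it exists for diagnostics only.

    Replicate r draws from the spawned child stream r of ``seed``, so
    replicates are reproducible independently and in any order.
    """
    if n_sims < 1:
        raise ValueError("need at least one replicate")
    work = len(list(tree.postorder())) * n_sites * n_sims
    if work > budget:
        raise SimulationSizeError(
            f"null simulation of {work} node-site-replicates exceeds budget {budget}"
        )
    root_mode = "stationary" if root_sequence is None else root_sequence
    streams = np.random.SeedSequence(seed).spawn(n_sims)
    tables: list[dict[tuple[int, str, str], int]] = []
    for child_seq in streams:
        rng = np.random.default_rng(child_seq)
        sim = simulate_alignment(tree, model, n_sites, root_mode=root_mode, seed=rng)
        if true_history_only:
            events = [e for e in sim.true_events if _keep(tree, e, exclude_clade)]
        else:
            engine = TreeLikelihood(tree, model, sim.alignment)
            rec = engine.ancestral_states()
            events = extract_substitution_events(
                tree,
                rec.map_sequences,
                sim.alignment,
                gene="null",
                exclude_clade=exclude_clade,
            )
        tables.append(dict(Counter((e.site, e.parent_state, e.child_state) for e in events)))
    return tables


def _keep(tree: PhyloTree, event: SubstitutionEvent, exclude_clade) -> bool:
    if exclude_clade is None:
        return True
    clade = tree.mrca({exclude_clade} if isinstance(exclude_clade, str) else set(exclude_clade))
    return not tree.in_clade(tree.node(event.branch), clade)


def test_recurrence_significance(
    observed_counts: dict[tuple[int, str, str], int],
    null_tables: list[dict[tuple[int, str, str], int]],
    gene: str = "gene",
    mode: str = "per-site",
    min_count: int = 2,
) -> list[RecurrenceRecord]:
    """Score every observed key with count >= ``min_count`` against the null.

    ``mode="per-site"`` compares the observed count at (site, X, Y) with
    the null count at the same key (the literal recurrence definition:
    more than once *at a given site*).  ``mode="per-type-max"`` is the
    conservative alternative: the null statistic is the maximum count of
    X->Y over all sites within each replicate.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown matching mode {mode!r}")
    n_sims = len(null_tables)
    if mode == "per-type-max":
        null_max: list[dict[tuple[str, str], int]] = []
        for table in null_tables:
            best: dict[tuple[str, str], int] = {}
            for (site, x, y), c in table.items():
                key = (x, y)
                if c > best.get(key, 0):
                    best[key] = c
            null_max.append(best)
    records = []
    for (site, x, y), k in sorted(observed_counts.items()):
        if k < min_count:
            continue
        if mode == "per-site":
            m = sum(1 for table in null_tables if table.get((site, x, y), 0) >= k)
        else:
            m = sum(1 for best in null_max if best.get((x, y), 0) >= k)
        p = (m + 1) / (n_sims + 1)
        records.append(
            RecurrenceRecord(
                gene=gene,
                site=site,
                parent_state=x,
                child_state=y,
                count=k,
                n_sims=n_sims,
                exceedance=m,
                p_value=p,
                significant=(m == 0),
                resolution_limited=(1.0 / (n_sims + 1) >= 0.001),
            )
        )
    return records


def recurrence_report(records: list[RecurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "site": r.site,
                "parent": r.parent_state,
                "child": r.child_state,
                "count": r.count,
                "n_sims": r.n_sims,
                "exceedance": r.exceedance,
                "p_value": r.p_value,
                "significant": r.significant,
                "resolution_limited": r.resolution_limited,
            }
            for r in records
        ],
        columns=[
            "gene", "site", "parent", "child", "count",
            "n_sims", "exceedance", "p_value", "significant", "resolution_limited",
        ],
    )
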