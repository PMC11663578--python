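"""End-to-end orchestration: one config in, a report bundle out.

Stage order follows the analysis logic: inputs -> gap trimming ->
branch-length re-estimation on the fixed topology -> ancestral
reconstruction -> branch-anchored events -> Monte Carlo recurrence ->
site-selection classification (codon genes) -> structure contact
categories -> interface-effect classification -> enrichment statistics.
Every stage reads its inputs from and writes its outputs to the run
directory, so stages can be re-run individually and a completed run is
fully described by its files plus the JSON manifest.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alphabets import GeneticCode
from .contacts import (
    classify_interface_effect,
    cofactor_binding_residues,
    interface_residues,
    load_packaged_ddg_table,
)
from .likelihood import TreeLikelihood, optimize_branch_lengths
from .models import SubstitutionModel
from .recurrence import (
    count_recurrences,
    recurrence_report,
    simulate_null_recurrences,
    test_recurrence_significance,
)
from .seqio import Alignment, read_fasta_alignment, trim_gap_columns, write_fasta
from .selection import (
    classify_site_selection,
    map_codon_events_ns,
    site_neutral_expectation,
)
from .stats import (
    compare_group_rates,
    hypergeom_overlap_test,
    length_adaptation_regression,
)
from .structures import read_structure
from .substmap import (
    events_to_frame,
    extract_substitution_events,
    invariant_sites,
    matrices_to_frame,
    protein_substitution_summary,
    tabulate_site_matrices,
)
from .synthetic import (
    ToyStructureSpec,
    generate_random_tree,
    generate_toy_structure,
    inject_convergent_events,
    simulate_alignment,
)
from .trees import PhyloTree, read_newick, write_newick

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is inconsistent."""


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of synthetic/real is active."""

    seed: int = 0
    outdir: str = "photoevol_run"
    # synthetic scenario (None -> real-input mode)
    synthetic: Optional[dict[str, Any]] = None
    # real inputs
    alignments: Optional[dict[str, str]] = None  # gene -> FASTA path
    tree: Optional[str] = None
    structures: Optional[dict[str, str]] = None  # id -> PDB path
    ddg_table: Optional[str] = None  # TSV path; None -> packaged fixture
    outgroup: Optional[list[str]] = None
    chain_pairs: list[list[str]] = field(default_factory=lambda: [["A", "B"]])
    # model
    model: dict[str, Any] = field(
        default_factory=lambda: {
            "matrix": "JTT",
            "frequencies": "+F",
            "gamma_alpha": 1.0,
            "n_categories": 4,
        }
    )
    # thresholds
    gap_trim: float = 0.9
    contact_cutoff: float = 4.0
    ddg_threshold: float = 0.5
    recurrence_n: int = 200
    recurrence_mode: str = "per-site"
    selection_threshold: float = 0.1
    optimize_branch_lengths: bool = True
    brlen_tol: float = 1e-3
    brlen_max_sweeps: int = 5

    def __post_init__(self):
        if self.synthetic is not None and self.alignments is not None:
            raise ConfigError("config mixes synthetic scenario and real inputs")
        if self.synthetic is None and self.alignments is None:
            self.synthetic = default_scenario()
        for name, value in (
            ("gap_trim", self.gap_trim),
            ("contact_cutoff", self.contact_cutoff),
            ("ddg_threshold", self.ddg_threshold),
            ("recurrence_n", self.recurrence_n),
        ):
            if value <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.alignments is not None:
            missing = [
                p
                for p in [self.tree, *(self.alignments or {}).values()]
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise ConfigError(f"missing input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def default_scenario() -> dict[str, Any]:
    """The packaged desk-scale synthetic study.

    50 leaves; three amino-acid genes (the lead one 200 sites) under
    JTT+F with 4 gamma categories; one 100-codon nucleotide gene under a
    transition-biased GTR; a toy two-chain structure; the packaged ddG
    table.  No convergence is injected, so recurrence runs under a pure
    model null.
    """
    return {
        "n_leaves": 50,
        "birth_rate": 1.0,
        "tree_height": 0.2,
        "aa_genes": {"g1": 200, "g2": 150, "g3": 100},
        "codon_genes": {"c1": 100},
        "inject": [],  # entries: {gene, site, x, y, n_branches}
        "structure": {
            "residues_per_chain": 6,
            "ligand_distance": 3.9,
            "contact_pair": [2, 3, 3.5],
        },
    }


def _build_aa_model(config: PipelineConfig, aln: Alignment) -> SubstitutionModel:
    m = config.model
    return SubstitutionModel.empirical(
        m.get("matrix", "JTT"),
        alignment=aln if m.get("frequencies", "+F") == "+F" else None,
        gamma_alpha=m.get("gamma_alpha", 1.0),
        n_categories=m.get("n_categories", 4),
    )


def _nt_model(gamma_alpha: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    S = np.array(
        [
            [0, 1, 2, 1],
            [1, 0, 1, 2],
            [2, 1, 0, 1],
            [1, 2, 1, 0],
        ],
        dtype=float,
    )
    pi = np.array([0.3, 0.2, 0.2, 0.3])
    return SubstitutionModel.gtr(S, pi, gamma_alpha=gamma_alpha, n_categories=n_categories)


def _well_separated_branches(
    tree: PhyloTree,
    n: int,
    max_clade_frac: float = 0.15,
    min_separation: float = 0.05,
    max_clade_size: int | None = None,
) -> list[str]:
    """n pairwise non-nested, well-separated branches for convergence injection.

    Candidates subtend small clades (so injected lineages stay
    independent rather than covering the tree) and are taken longest
    first.  Separation is enforced as a minimum path length
    (substitutions/site) between the parent nodes of any two chosen
    branches — adjacent origins would otherwise be merged into one
    ancestral event by reconstruction.  The separation requirement is
    relaxed geometrically if the tree cannot accommodate it.
    """
    n_leaves = tree.n_leaves()
    cap = (
        max_clade_size
        if max_clade_size is not None
        else max(2, int(np.ceil(max_clade_frac * n_leaves)))
    )
    depth: dict[str, float] = {tree.root.name: 0.0}
    order: dict[str, int] = {}
    ancestors: dict[str, list[str]] = {tree.root.name: [tree.root.name]}
    for i, node in enumerate(tree.preorder()):
        order[node.name] = i
        if not node.is_root:
            depth[node.name] = depth[node.parent.name] + node.length
            ancestors[node.name] = ancestors[node.parent.name] + [node.name]

    def path_dist(a: str, b: str) -> float:
        pa, pb = ancestors[a], ancestors[b]
        common = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            common += 1
        mrca = pa[common - 1]
        return depth[a] + depth[b] - 2 * depth[mrca]

    candidates = sorted(
        (
            node
            for node in tree.postorder()
            if not node.is_root and len(tree.descendant_leaves(node)) <= cap
        ),
        key=lambda nd: -(nd.length or 0.0),
    )
    sep = min_separation
    while True:
        chosen: list = []
        for node in candidates:
            if any(
                tree.in_clade(node, c) or tree.in_clade(c, node) for c in chosen
            ):
                continue
            if any(
                path_dist(node.parent.name, c.parent.name) < sep for c in chosen
            ):
                continue
            chosen.append(node)
            if len(chosen) == n:
                return [c.name for c in chosen]
        if sep < 1e-6:
            raise ValueError(f"could not find {n} non-nested branches")
        sep /= 2


# -- stages ---------------------------------------------------------------

def stage_inputs(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    """Materialize inputs (generate synthetic or load real) into the run dir."""
    outdir.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    info: dict[str, Any] = {"genes": {}}
    if config.synthetic is not None:
        sc = config.synthetic
        tree = generate_random_tree(
            sc.get("n_leaves", 50),
            sc.get("birth_rate", 1.0),
            seed=np.random.default_rng(rng_root.spawn(1)[0]),
            height=sc.get("tree_height", 0.5),
        )
        write_newick(tree, outdir / "tree.nwk")
        streams = iter(rng_root.spawn(64)[1:])
        genes = {**sc.get("aa_genes", {}), **sc.get("codon_genes", {})}
        for gene, size in sc.get("aa_genes", {}).items():
            model = SubstitutionModel.empirical(
                config.model.get("matrix", "JTT"),
                gamma_alpha=config.model.get("gamma_alpha", 1.0),
                n_categories=config.model.get("n_categories", 4),
            )
            sim = simulate_alignment(
                tree, model, size, seed=np.random.default_rng(next(streams)), gene=gene
            )
            aln = sim.alignment
            for inj in sc.get("inject", []):
                if inj.get("gene") != gene:
                    continue
                branches = inj.get("branches") or _well_separated_branches(
                    tree, inj["n_branches"]
                )
                aln = inject_convergent_events(
                    aln, tree, inj["site"], inj["x"], inj["y"], branches, model,
                    seed=np.random.default_rng(next(streams)),
                )
            write_fasta(aln, outdir / f"{gene}_alignment.fasta")
            info["genes"][gene] = {"layer": "amino-acid", "n_sites": size}
        for gene, size in sc.get("codon_genes", {}).items():
            sim = simulate_alignment(
                tree,
                _nt_model(),
                size * 3,
                seed=np.random.default_rng(next(streams)),
                gene=gene,
            )
            write_fasta(sim.alignment, outdir / f"{gene}_alignment.fasta")
            info["genes"][gene] = {"layer": "codon", "n_sites": size}
        st = sc.get("structure", {})
        spec = ToyStructureSpec(
            residues_per_chain=st.get("residues_per_chain", 6),
            ligand_distance=st.get("ligand_distance", 3.9),
            contact_pair=tuple(st["contact_pair"]) if st.get("contact_pair") else None,
        )
        (outdir / "structure.pdb").write_text(generate_toy_structure(spec))
        load_packaged_ddg_table().to_csv(outdir / "ddg.tsv", sep="\t", index=False)
    else:
        tree = read_newick(config.tree)
        write_newick(tree, outdir / "tree.nwk")
        for gene, path in config.alignments.items():
            aln = read_fasta_alignment(path, "amino-acid")
            write_fasta(aln, outdir / f"{gene}_alignment.fasta")
            info["genes"][gene] = {"layer": "amino-acid", "n_sites": aln.n_sites}
        for sid, path in (config.structures or {}).items():
            (outdir / "structure.pdb").write_text(Path(path).read_text())
        ddg = (
            pd.read_csv(config.ddg_table, sep="\t")
            if config.ddg_table
            else load_packaged_ddg_table()
        )
        ddg.to_csv(outdir / "ddg.tsv", sep="\t", index=False)
    (outdir / "genes.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return info


def _gene_info(outdir: Path) -> dict[str, Any]:
    return json.loads((outdir / "genes.json").read_text())


def stage_trim(config: PipelineConfig, outdir: Path) -> None:
    info = _gene_info(outdir)
    for gene, meta in info["genes"].items():
        alphabet = "codon" if meta["layer"] == "codon" else "amino-acid"
        aln = read_fasta_alignment(outdir / f"{gene}_alignment.fasta", alphabet)
        trimmed, column_map = trim_gap_columns(aln, config.gap_trim)
        write_fasta(trimmed, outdir / f"{gene}_trimmed.fasta")
        pd.DataFrame(
            {"trimmed_site": np.arange(1, len(column_map) + 1), "original_site": column_map}
        ).to_csv(outdir / f"{gene}_column_map.tsv", sep="\t", index=False)


def _load_gene(config: PipelineConfig, outdir: Path, gene: str, meta) -> tuple[Alignment, SubstitutionModel]:
    alphabet = "codon" if meta["layer"] == "codon" else "amino-acid"
    aln = read_fasta_alignment(outdir / f"{gene}_trimmed.fasta", alphabet)
    if meta["layer"] == "codon":
        model = _nt_model(
            config.model.get("gamma_alpha", 1.0), config.model.get("n_categories", 4)
        )
    else:
        model = _build_aa_model(config, aln)
    return aln, model


def stage_branch_lengths(config: PipelineConfig, outdir: Path) -> None:
    info = _gene_info(outdir)
    tree = read_newick(outdir / "tree.nwk")
    for gene, meta in info["genes"].items():
        aln, model = _load_gene(config, outdir, gene, meta)
        if config.optimize_branch_lengths:
            if meta["layer"] == "codon":
                nt = Alignment(dict(aln.records), "nucleotide")
                opt, _, _ = optimize_branch_lengths(
                    tree, nt, model, tol=config.brlen_tol,
                    max_sweeps=config.brlen_max_sweeps,
                )
            else:
                opt, _, _ = optimize_branch_lengths(
                    tree, aln, model, tol=config.brlen_tol,
                    max_sweeps=config.brlen_max_sweeps,
                )
        else:
            opt = tree
        write_newick(opt, outdir / f"{gene}_tree.nwk")


def stage_asr(config: PipelineConfig, outdir: Path) -> None:
    info = _gene_info(outdir)
    for gene, meta in info["genes"].items():
        aln, model = _load_gene(config, outdir, gene, meta)
        if meta["layer"] == "codon":
            aln = Alignment(dict(aln.records), "nucleotide")
        tree = read_newick(outdir / f"{gene}_tree.nwk")
        rec = TreeLikelihood(tree, model, aln).ancestral_states()
        anc = Alignment(dict(rec.map_sequences), aln.alphabet)
        write_fasta(anc, outdir / f"{gene}_ancestral.fasta")


def stage_events(config: PipelineConfig, outdir: Path) -> None:
    info = _gene_info(outdir)
    summaries: dict[str, list] = {}
    lengths: dict[str, int] = {}
    inv_sets: dict[str, set[int]] = {}
    for gene, meta in info["genes"].items():
        if meta["layer"] == "codon":
            continue
        aln = read_fasta_alignment(outdir / f"{gene}_trimmed.fasta", "amino-acid")
        tree = read_newick(outdir / f"{gene}_tree.nwk")
        anc = read_fasta_alignment(outdir / f"{gene}_ancestral.fasta", "amino-acid")
        events = extract_substitution_events(
            tree,
            dict(anc.records),
            aln,
            gene=gene,
            exclude_clade=set(config.outgroup) if config.outgroup else None,
        )
        events_to_frame(events).to_csv(
            outdir / f"{gene}_events.tsv", sep="\t", index=False
        )
        matrices_to_frame(tabulate_site_matrices(events)).to_csv(
            outdir / f"{gene}_site_matrices.tsv", sep="\t", index=False
        )
        invariant, variant, indeterminate = invariant_sites(aln)
        pd.DataFrame(
            sorted(
                [(s, "invariant") for s in invariant]
                + [(s, "variant") for s in variant]
                + [(s, "indeterminate") for s in indeterminate]
            ),
            columns=["site", "status"],
        ).to_csv(outdir / f"{gene}_invariant_sites.tsv", sep="\t", index=False)
        summaries[gene] = events
        lengths[gene] = aln.n_sites
        inv_sets[gene] = invariant
    if summaries:
        protein_substitution_summary(summaries, lengths, inv_sets).to_csv(
            outdir / "protein_summary.tsv",
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )


def stage_recurrence(config: PipelineConfig, outdir: Path) -> None:
    info = _gene_info(outdir)
    frames = []
    for gene, meta in info["genes"].items():
        if meta["layer"] == "codon":
            continue
        aln = read_fasta_alignment(outdir / f"{gene}_trimmed.fasta", "amino-acid")
        tree = read_newick(outdir / f"{gene}_tree.nwk")
        anc = read_fasta_alignment(outdir / f"{gene}_ancestral.fasta", "amino-acid")
        events_df = pd.read_csv(outdir / f"{gene}_events.tsv", sep="\t")
        observed: dict[tuple[int, str, str], int] = {}
        for _, row in events_df.iterrows():
            key = (int(row["site"]), row["parent"], row["child"])
            observed[key] = observed.get(key, 0) + 1
        _, model = _load_gene(config, outdir, gene, meta)
        root_seq = anc.records[tree.root.name]
        gene_seed = int(
            np.random.SeedSequence(
                config.seed, spawn_key=(zlib.crc32(gene.encode()),)
            ).generate_state(1)[0] % (2**31)
        )
        null = simulate_null_recurrences(
            tree,
            model,
            root_seq,
            aln.n_sites if aln.alphabet != "codon" else aln.n_sites * 3,
            config.recurrence_n,
            seed=gene_seed,
            exclude_clade=set(config.outgroup) if config.outgroup else None,
        )
        records = test_recurrence_significance(
            observed, null, gene=gene, mode=config.recurrence_mode
        )
        frames.append(recurrence_report(records))
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "recurrence.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )


def stage_selection(config: PipelineConfig, outdir: Path) -> None:
    info = _gene_info(outdir)
    frames = []
    code = GeneticCode(11)
    for gene, meta in info["genes"].items():
        if meta["layer"] != "codon":
            continue
        aln = read_fasta_alignment(outdir / f"{gene}_trimmed.fasta", "codon")
        nt_aln = Alignment(dict(aln.records), "nucleotide")
        tree = read_newick(outdir / f"{gene}_tree.nwk")
        anc = read_fasta_alignment(outdir / f"{gene}_ancestral.fasta", "nucleotide")
        counts = map_codon_events_ns(
            tree,
            dict(anc.records),
            nt_aln,
            code,
            exclude_clade=set(config.outgroup) if config.outgroup else None,
        )
        model = _nt_model(
            config.model.get("gamma_alpha", 1.0), config.model.get("n_categories", 4)
        )
        p_n = site_neutral_expectation(tree, dict(anc.records), nt_aln, code, model)
        table = classify_site_selection(counts, p_n, config.selection_threshold)
        table.insert(0, "gene", gene)
        frames.append(table)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "selection.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )


def stage_contacts(config: PipelineConfig, outdir: Path) -> None:
    pdb_path = outdir / "structure.pdb"
    if not pdb_path.exists():
        return
    structure = read_structure(pdb_path)
    rows = []
    cof = cofactor_binding_residues(structure, cutoff=config.contact_cutoff)
    for chain, num, icode in sorted(cof.members):
        rows.append(
            {"chain": chain, "resnum": num, "icode": icode, "category": "cofactor-binding"}
        )
    pairs = [tuple(p) for p in config.chain_pairs if all(c in structure.chains for c in p)]
    for pair, cset in interface_residues(structure, pairs, config.contact_cutoff).items():
        for chain, num, icode in sorted(cset.members):
            rows.append(
                {
                    "chain": chain,
                    "resnum": num,
                    "icode": icode,
                    "category": f"interface:{pair[0]}-{pair[1]}",
                }
            )
    pd.DataFrame(rows, columns=["chain", "resnum", "icode", "category"]).to_csv(
        outdir / "contacts.tsv", sep="\t", index=False
    )


def stage_effects(config: PipelineConfig, outdir: Path) -> None:
    ddg = pd.read_csv(outdir / "ddg.tsv", sep="\t")
    table, counts = classify_interface_effect(ddg, config.ddg_threshold)
    table.to_csv(outdir / "effects.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    counts.rename_axis("classification").reset_index(name="count").to_csv(
        outdir / "effect_counts.tsv", sep="\t", index=False
    )


def stage_enrichment(config: PipelineConfig, outdir: Path) -> None:
    results: dict[str, Any] = {}
    info = _gene_info(outdir)
    aa_genes = [g for g, m in info["genes"].items() if m["layer"] != "codon"]
    if (outdir / "recurrence.tsv").exists() and aa_genes:
        rec = pd.read_csv(outdir / "recurrence.tsv", sep="\t")
        gene = aa_genes[0]
        inv = pd.read_csv(outdir / f"{gene}_invariant_sites.tsv", sep="\t")
        universe = set(inv["site"])
        variant = set(inv.loc[inv["status"] == "variant", "site"])
        rec_g = rec[rec["gene"] == gene]
        recurrent = set(rec_g["site"])
        significant = set(rec_g.loc[rec_g["significant"], "site"])
        test = hypergeom_overlap_test(universe, variant, recurrent, "enrichment")
        results["recurrent_in_variant"] = asdict(test)
        results["n_significant_recurrent_sites"] = len(significant)
    if (outdir / "effects.tsv").exists():
        eff = pd.read_csv(outdir / "effects.tsv", sep="\t")
        # D1 is chain A of the PSII complex: restrict to PSII (Psb) rows
        # whose interface involves chain A
        if "subunit" in eff.columns:
            d1 = eff[
                eff["subunit"].str.startswith("Psb")
                & eff["interface"].str.contains("A")
            ]
        else:
            d1 = eff.iloc[0:0]
        if len(d1) >= 2:
            cmp = compare_group_rates(d1["ddg_kcal_mol"].to_numpy(), mu0=0.0)
            results["d1_interface_ddg_vs_zero"] = asdict(cmp)
        stab = eff.loc[eff["classification"] == "stabilizing", "ddg_kcal_mol"]
        dest = eff.loc[eff["classification"] == "destabilizing", "ddg_kcal_mol"]
        if len(stab) >= 2 and len(dest) >= 2:
            results["stabilizing_vs_destabilizing"] = asdict(
                compare_group_rates(dest.to_numpy(), stab.to_numpy())
            )
    if (outdir / "protein_summary.tsv").exists():
        summary = pd.read_csv(outdir / "protein_summary.tsv", sep="\t")
        if len(summary) >= 3:
            reg = length_adaptation_regression(
                summary["length"].to_numpy(), summary["n_substitutions"].to_numpy()
            )
            results["substitutions_vs_length"] = asdict(reg)
    (outdir / "enrichment.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float)
    )


STAGES = [
    ("inputs", stage_inputs),
    ("trim", stage_trim),
    ("brlen", stage_branch_lengths),
    ("asr", stage_asr),
    ("events", stage_events),
    ("recur", stage_recurrence),
    ("select", stage_selection),
    ("contacts", stage_contacts),
    ("effects", stage_effects),
    ("enrich", stage_enrichment),
]


def run_full_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> Path:
    """Run every stage in order; write a machine-readable manifest.

    A stage failure halts downstream stages; partial outputs are kept
    and the manifest records the failed stage before the error is
    re-raised.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, Path)
        },
        "stages": [],
    }
    try:
        for name, fn in STAGES:
            t0 = time.perf_counter()
            fn(config, out)
            manifest["stages"].append(
                {"name": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
            )
    except Exception as exc:
        manifest["stages"].append({"name": name, "status": f"failed: {exc}"})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
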