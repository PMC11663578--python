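"""Generator properties: Yule trees, simulated histories, injection,
toy structures — all pure functions of (parameters, seed)."""

import numpy as np
import pytest

import photoevol as pe
from photoevol.synthetic import (
    SimulationSizeError,
    ToyStructureSpec,
    generate_toy_structure,
)


class TestYuleTrees:
    def test_two_leaves_is_a_cherry(self):
        t = pe.generate_random_tree(2, seed=0)
        assert t.n_leaves() == 2 and len(t.root.children) == 2

    def test_binary_rooted_node_count(self):
        t = pe.generate_random_tree(50, seed=1)
        nodes = list(t.postorder())
        internal = [n for n in nodes if not n.is_leaf]
        assert len(nodes) == 99 and len(internal) == 49

    def test_deterministic_newick_under_seed(self):
        a = pe.generate_random_tree(12, seed=7, height=0.3).newick()
        b = pe.generate_random_tree(12, seed=7, height=0.3).newick()
        assert a == b

    def test_height_rescaling(self):
        t = pe.generate_random_tree(10, seed=2, height=0.25)
        for leaf in t.leaves():
            depth = 0.0
            node = leaf
            while not node.is_root:
                depth += node.length
                node = node.parent
            assert depth == pytest.approx(0.25)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            pe.generate_random_tree(1, seed=0)


class TestSimulation:
    def test_zero_branch_lengths_copy_root(self, jtt_g4):
        tree = pe.parse_newick("(A:0,B:0,C:0);")
        sim = pe.simulate_alignment(tree, jtt_g4, 20, root_mode="MKELVWRTYHGASDNQCIFP", seed=0)
        assert all(s == "MKELVWRTYHGASDNQCIFP" for s in sim.alignment.records.values())
        assert sim.true_events == []

    def test_long_branch_reaches_stationarity(self, equ20):
        tree = pe.parse_newick("(A:50,B:50);")
        sim = pe.simulate_alignment(tree, equ20, 10000, seed=1)
        freqs = np.array(
            [sim.alignment.records["A"].count(s) for s in equ20.states]
        ) / 10000
        se = np.sqrt(0.05 * 0.95 / 10000)
        assert np.all(np.abs(freqs - 0.05) < 3 * se + 1e-12)

    def test_two_leaf_mismatch_matches_closed_form(self, equ20):
        t1, t2, n = 0.15, 0.25, 20000
        tree = pe.parse_newick(f"(A:{t1},B:{t2});")
        sim = pe.simulate_alignment(tree, equ20, n, seed=2)
        a, b = (sim.alignment.records[x] for x in ("A", "B"))
        p_obs = sum(x != y for x, y in zip(a, b)) / n
        P = equ20.transition_matrix(t1 + t2)
        p_exp = 1 - float(equ20.pi @ np.diag(P))
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_true_events_reconcile_with_endpoints(self, jtt_g4):
        tree = pe.generate_random_tree(15, seed=3, height=0.5)
        sim = pe.simulate_alignment(tree, jtt_g4, 100, seed=4)
        seqs = dict(sim.alignment.records) | sim.node_sequences
        expected = set()
        for node in tree.postorder():
            if node.is_root:
                continue
            p, c = seqs[node.parent.name], seqs[node.name]
            for s, (x, y) in enumerate(zip(p, c), start=1):
                if x != y:
                    expected.add((s, node.name, x, y))
        got = {(e.site, e.branch, e.parent_state, e.child_state) for e in sim.true_events}
        assert got == expected

    def test_budget_guard(self, jtt_g4):
        tree = pe.generate_random_tree(10, seed=5)
        with pytest.raises(SimulationSizeError):
            pe.simulate_alignment(tree, jtt_g4, 10**9, seed=0)

    def test_byte_identical_under_seed(self, jtt_g4):
        tree = pe.generate_random_tree(10, seed=6, height=0.4)
        a = pe.simulate_alignment(tree, jtt_g4, 50, seed=11)
        b = pe.simulate_alignment(tree, jtt_g4, 50, seed=11)
        assert a.alignment.records == b.alignment.records
        assert a.node_sequences == b.node_sequences


class TestInjection:
    def test_descendants_carry_injected_state(self, jtt_g4):
        tree = pe.generate_random_tree(20, seed=7, height=0.4)
        sim = pe.simulate_alignment(tree, jtt_g4, 30, seed=8)
        from photoevol.pipeline import _well_separated_branches

        branches = _well_separated_branches(tree, 4)
        out = pe.inject_convergent_events(
            sim.alignment, tree, 5, "E", "A", branches, jtt_g4, seed=9
        )
        injected_leaves = set().union(
            *(tree.descendant_leaves(tree.node(b)) for b in branches)
        )
        for leaf, seq in out.records.items():
            if leaf in injected_leaves:
                assert seq[4] == "A"
        # other columns untouched
        for leaf in out.records:
            assert out.records[leaf][:4] == sim.alignment.records[leaf][:4]
            assert out.records[leaf][5:] == sim.alignment.records[leaf][5:]

    def test_no_branches_is_identity(self, jtt_g4):
        tree = pe.generate_random_tree(8, seed=10, height=0.3)
        sim = pe.simulate_alignment(tree, jtt_g4, 10, seed=11)
        out = pe.inject_convergent_events(
            sim.alignment, tree, 3, "E", "A", [], jtt_g4, seed=12
        )
        assert out.records == sim.alignment.records

    def test_nested_branches_rejected(self, jtt_g4):
        tree = pe.parse_newick("((A:1,B:1)N0:1,C:1)R;")
        aln = pe.Alignment({x: "MKE" for x in "ABC"})
        with pytest.raises(ValueError, match="nested"):
            pe.inject_convergent_events(aln, tree, 1, "E", "A", ["N0", "A"], jtt_g4)

    def test_full_pipeline_recovers_injected_recurrence(self, jtt_g4):
        from photoevol.pipeline import _well_separated_branches
        from photoevol.recurrence import count_recurrences, recurrent_keys

        tree = pe.generate_random_tree(30, seed=13, height=0.5)
        sim = pe.simulate_alignment(tree, jtt_g4, 60, seed=14)
        branches = _well_separated_branches(tree, 6)
        aln = pe.inject_convergent_events(
            sim.alignment, tree, 10, "E", "A", branches, jtt_g4, seed=15
        )
        rec = pe.marginal_ancestral_states(tree, jtt_g4, aln)
        events = pe.extract_substitution_events(tree, rec.map_sequences, aln)
        keys = recurrent_keys(count_recurrences(events))
        assert keys.get((10, "E", "A"), 0) >= 2


class TestToyStructures:
    def test_emitted_distances_match_spec(self):
        spec = ToyStructureSpec(
            residues_per_chain=4, ligand_distance=2.7, contact_pair=(1, 2, 3.3)
        )
        st = pe.read_structure(generate_toy_structure(spec))
        lig = st.hetero_residues()[0].atoms[0]
        anchor = [a for a in st.chains["A"][0].atoms if a.name == "CA"][0]
        assert np.linalg.norm(np.subtract(anchor.xyz, lig.xyz)) == pytest.approx(2.7, abs=1e-3)
        ca_a = [a for a in st.chains["A"][0].atoms if a.name == "CA"][0]
        ca_b = [
            a
            for r in st.chains["B"]
            if r.number == 2
            for a in r.atoms
            if a.name == "CA"
        ][0]
        assert np.linalg.norm(np.subtract(ca_a.xyz, ca_b.xyz)) == pytest.approx(3.3, abs=1e-3)

    def test_infeasible_request_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_structure(ToyStructureSpec(ligand_distance=-1.0))

    def test_far_chains_have_empty_interface(self):
        from photoevol.contacts import interface_residues

        st = pe.read_structure(generate_toy_structure(ToyStructureSpec()))
        assert interface_residues(st, [("A", "B")])[("A", "B")].members == set()
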