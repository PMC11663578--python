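"""Pruning likelihood, marginal ASR and branch-length optimization,
checked against closed forms and exhaustive-enumeration oracles."""

import numpy as np
import pytest

import photoevol as pe
from photoevol.likelihood import PairingError, TreeLikelihood

from conftest import (
    brute_force_node_posterior,
    brute_force_site_likelihood,
    random_nt_model,
)


def random_tree_newick(n_leaves, rng):
    """Random binary topology with uniform branch lengths, as Newick."""
    t = pe.generate_random_tree(n_leaves, seed=rng, height=float(rng.uniform(0.1, 0.6)))
    return t


class TestLogLikelihood:
    def test_single_leaf_is_log_pi(self):
        m = pe.SubstitutionModel.equal_rates(4)
        tree = pe.PhyloTree(pe.trees.TreeNode("A"))
        aln = pe.Alignment({"A": "C"}, "nucleotide")
        _, total = pe.tree_log_likelihood(tree, m, aln)
        assert total == pytest.approx(np.log(0.25))

    def test_two_leaf_closed_form(self):
        rng = np.random.default_rng(4)
        m = random_nt_model(rng)
        t1, t2 = 0.13, 0.29
        tree = pe.parse_newick(f"(A:{t1},B:{t2});")
        aln = pe.Alignment({"A": "A", "B": "G"}, "nucleotide")
        _, total = pe.tree_log_likelihood(tree, m, aln)
        P1, P2 = m.transition_matrix(t1), m.transition_matrix(t2)
        direct = sum(m.pi[x] * P1[x, 0] * P2[x, 2] for x in range(4))
        assert total == pytest.approx(np.log(direct), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_leaves = int(rng.integers(4, 6))
        tree = random_tree_newick(n_leaves, rng)
        m = random_nt_model(rng, n_categories=int(rng.integers(1, 3)))
        sim = pe.simulate_alignment(tree, m, 10, seed=rng)
        site_ll, _ = pe.tree_log_likelihood(tree, m, sim.alignment)
        for site in range(10):
            oracle = brute_force_site_likelihood(tree, m, sim.alignment, site)
            assert site_ll[site] == pytest.approx(oracle, abs=1e-10)

    def test_gaps_and_ambiguity_as_missing(self):
        rng = np.random.default_rng(7)
        m = random_nt_model(rng)
        tree = pe.parse_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        aln = pe.Alignment({"A": "A-R", "B": "ANY", "C": "AC-"}, "nucleotide")
        site_ll, _ = pe.tree_log_likelihood(tree, m, aln)
        for site in range(3):
            oracle = brute_force_site_likelihood(tree, m, aln, site)
            assert site_ll[site] == pytest.approx(oracle, abs=1e-10)

    def test_missing_leaf_sequence_raises(self):
        m = pe.SubstitutionModel.equal_rates(4)
        tree = pe.parse_newick("(A:0.1,B:0.2);")
        aln = pe.Alignment({"A": "C"}, "nucleotide")
        with pytest.raises(PairingError):
            pe.tree_log_likelihood(tree, m, aln)


class TestMarginalASR:
    def test_star_tree_posterior_matches_enumeration(self):
        rng = np.random.default_rng(11)
        m = random_nt_model(rng)
        tree = pe.parse_newick("(A:0.1,B:0.1,C:0.1)R;")
        aln = pe.Alignment({"A": "A", "B": "A", "C": "C"}, "nucleotide")
        rec = pe.marginal_ancestral_states(tree, m, aln)
        oracle = brute_force_node_posterior(tree, m, aln, 0, "R")
        assert np.allclose(rec.posteriors["R"][0], oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_internal_posteriors_match_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        tree = random_tree_newick(4, rng)
        m = random_nt_model(rng, n_categories=2)
        sim = pe.simulate_alignment(tree, m, 6, seed=rng)
        rec = pe.marginal_ancestral_states(tree, m, sim.alignment)
        for node, post in rec.posteriors.items():
            for site in range(6):
                oracle = brute_force_node_posterior(
                    tree, m, sim.alignment, site, node
                )
                assert np.allclose(post[site], oracle, atol=1e-10)

    def test_posteriors_normalized(self, jtt_g4):
        tree = pe.generate_random_tree(8, seed=5, height=0.4)
        sim = pe.simulate_alignment(tree, jtt_g4, 30, seed=6)
        rec = pe.marginal_ancestral_states(tree, jtt_g4, sim.alignment)
        for post in rec.posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)

    def test_identical_leaves_give_map_state(self, equ20):
        tree = pe.parse_newick("((A:0.05,B:0.1):0.05,(C:0.08,D:0.02):0.04);")
        aln = pe.Alignment({x: "W" for x in "ABCD"})
        rec = pe.marginal_ancestral_states(tree, equ20, aln)
        assert all(s == "W" for s in rec.map_sequences.values())

    def test_root_accuracy_improves_with_shorter_branches(self, jtt_g4):
        accuracies = []
        for height in (0.5, 0.2, 0.05):
            correct = total = 0
            for seed in range(3):
                tree = pe.generate_random_tree(12, seed=40 + seed, height=height)
                sim = pe.simulate_alignment(tree, jtt_g4, 150, seed=60 + seed)
                rec = pe.marginal_ancestral_states(tree, jtt_g4, sim.alignment)
                truth = sim.node_sequences[tree.root.name]
                est = rec.map_sequences[tree.root.name]
                correct += sum(a == b for a, b in zip(truth, est))
                total += len(truth)
            accuracies.append(correct / total)
        assert accuracies[0] < accuracies[1] < accuracies[2]


class TestBranchLengthOptimization:
    def test_two_leaf_matches_analytic_distance(self, equ20):
        # equal-rates chain: ML total path length is
        # -(19/20) ln(1 - (20/19) p) at observed mismatch fraction p
        tree = pe.parse_newick("(A:0.2,B:0.2);")
        sim = pe.simulate_alignment(tree, equ20, 5000, seed=3)
        a, b = (sim.alignment.records[x] for x in ("A", "B"))
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        expected = -(19 / 20) * np.log(1 - (20 / 19) * p)
        opt, _, converged = pe.optimize_branch_lengths(tree, sim.alignment, equ20)
        assert converged
        total = sum(c.length for c in opt.root.children)
        assert total == pytest.approx(expected, rel=0.02)

    def test_recovers_simulated_lengths(self):
        m = pe.SubstitutionModel.empirical("JTT")
        tree = pe.generate_random_tree(10, seed=9, height=0.4)
        sim = pe.simulate_alignment(tree, m, 5000, seed=10)
        # start from deliberately wrong lengths
        start = tree.copy()
        for node in start.postorder():
            if not node.is_root:
                node.length = 0.1
        opt, _, _ = pe.optimize_branch_lengths(start, sim.alignment, m, tol=1e-4)
        true_lengths = {
            n.name: n.length for n in tree.postorder() if not n.is_root
        }
        rel_err = [
            abs(opt.node(name).length - t) / t
            for name, t in true_lengths.items()
            if t > 1e-3
        ]
        assert np.median(rel_err) < 0.15

    def test_identical_sequences_drive_lengths_to_zero(self, equ20):
        tree = pe.parse_newick("((A:0.3,B:0.2):0.1,C:0.4);")
        aln = pe.Alignment({x: "WLKMR" for x in "ABC"})
        opt, _, _ = pe.optimize_branch_lengths(tree, aln, equ20)
        for node in opt.postorder():
            if not node.is_root:
                assert node.length < 1e-4

    def test_log_likelihood_never_decreases(self, jtt_g4):
        tree = pe.generate_random_tree(8, seed=21, height=0.3)
        sim = pe.simulate_alignment(tree, jtt_g4, 200, seed=22)
        _, before = pe.tree_log_likelihood(tree, jtt_g4, sim.alignment)
        _, after, _ = pe.optimize_branch_lengths(tree, sim.alignment, jtt_g4, tol=1e-4)
        assert after >= before - 1e-9
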