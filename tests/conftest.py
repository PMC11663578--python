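"""Shared fixtures: small models, trees and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import photoevol as pe
from photoevol.alphabets import compatible_states


@pytest.fixture(scope="session")
def jtt_g4():
    return pe.SubstitutionModel.empirical("JTT", gamma_alpha=1.0, n_categories=4)


@pytest.fixture(scope="session")
def equ20():
    return pe.SubstitutionModel.equal_rates(20)


def random_nt_model(rng: np.random.Generator, n_categories: int = 1):
    """A random reversible 4-state model for enumeration oracles."""
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    S[iu] = rng.uniform(0.2, 3.0, size=len(iu[0]))
    S = S + S.T
    pi = rng.dirichlet(np.full(4, 5.0))
    rates = weights = None
    if n_categories > 1:
        rates = rng.uniform(0.2, 2.0, size=n_categories)
        weights = rng.dirichlet(np.full(n_categories, 3.0))
    return pe.SubstitutionModel(S, pi, rates, weights, name="rand")


def brute_force_site_likelihood(tree, model, aln, site):
    """Enumerate every assignment of states to internal nodes (and
    compatible leaf states) — the exhaustive oracle for pruning."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    k = model.k
    total = 0.0
    for c in range(model.n_categories):
        P = {
            n.name: model.transition_matrix(n.length, c)
            for n in nodes
            if not n.is_root
        }
        cat_total = 0.0
        leaf_opts = {
            n.name: list(compatible_states(aln.records[n.name][site], model.states))
            for n in nodes
            if n.is_leaf
        }
        for assign in itertools.product(range(k), repeat=len(internal)):
            states = {n.name: s for n, s in zip(internal, assign)}
            prob = model.pi[states[tree.root.name]]
            ok = True
            for n in nodes:
                if n.is_root:
                    continue
                ps = states[n.parent.name]
                if n.is_leaf:
                    prob *= sum(P[n.name][ps, s] for s in leaf_opts[n.name])
                else:
                    prob *= P[n.name][ps, states[n.name]]
                if prob == 0.0:
                    ok = False
                    break
            if ok:
                cat_total += prob
        total += model.weights[c] * cat_total
    return np.log(total)


def brute_force_node_posterior(tree, model, aln, site, node_name):
    """Exhaustive marginal posterior of one internal node at one site,
    mixed over rate categories by their posterior weights."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    k = model.k
    joint = np.zeros(k)
    for c in range(model.n_categories):
        P = {
            n.name: model.transition_matrix(n.length, c)
            for n in nodes
            if not n.is_root
        }
        leaf_opts = {
            n.name: list(compatible_states(aln.records[n.name][site], model.states))
            for n in nodes
            if n.is_leaf
        }
        for assign in itertools.product(range(k), repeat=len(internal)):
            states = {n.name: s for n, s in zip(internal, assign)}
            prob = model.pi[states[tree.root.name]]
            for n in nodes:
                if n.is_root:
                    continue
                ps = states[n.parent.name]
                if n.is_leaf:
                    prob *= sum(P[n.name][ps, s] for s in leaf_opts[n.name])
                else:
                    prob *= P[n.name][ps, states[n.name]]
            joint[states[node_name]] += model.weights[c] * prob
    return joint / joint.sum()
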