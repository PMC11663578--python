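"""Felsenstein pruning, branch-length optimization and marginal ASR.

The engine indexes a :class:`~photoevol.trees.PhyloTree` into postorder
arrays and keeps per-node conditional likelihoods of shape
(categories, sites, states) with per-(category, site) log-scaling, so
trees with many leaves never underflow.  Marginal ancestral posteriors
use the standard two-pass (inside/outside) algorithm; rate categories
are mixed by their per-site posterior weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alphabets import compatible_states
from .models import SubstitutionModel
from .seqio import Alignment
from .trees import PhyloTree, TreeNode

_TINY = 1e-300


class PairingError(ValueError):
    """A tree leaf has no sequence in the alignment (or alphabet mismatch)."""


@dataclass
class AncestralReconstruction:
    """Marginal ancestral states for every internal node.

    ``posteriors[name]`` is an (n_sites, k) category-mixed posterior;
    ``map_sequences[name]`` the per-site maximum-a-posteriori states
    (ties broken toward the lowest alphabet index).
    ``category_weights`` holds per-site posterior weights of the rate
    categories, used for the mixing.
    """

    states: str
    posteriors: dict[str, np.ndarray]
    map_sequences: dict[str, str]
    site_log_likelihood: np.ndarray
    total_log_likelihood: float
    category_weights: np.ndarray


class TreeLikelihood:
    """Pruning-algorithm workhorse bound to one (tree, model, alignment)."""

    def __init__(self, tree: PhyloTree, model: SubstitutionModel, aln: Alignment):
        if model.k == 4 and aln.alphabet not in ("nucleotide", "codon"):
            raise PairingError("nucleotide model requires a nucleotide alignment")
        if model.k == 20 and aln.alphabet != "amino-acid":
            raise PairingError("amino-acid model requires an amino-acid alignment")
        self.tree = tree
        self.model = model
        self.aln = aln
        self.n_sites = len(next(iter(aln.records.values())))

        self.nodes: list[TreeNode] = list(tree.postorder())
        self.index = {n.name: i for i, n in enumerate(self.nodes)}
        self.parent = np.full(len(self.nodes), -1)
        self.children: list[list[int]] = [[] for _ in self.nodes]
        self.lengths = np.zeros(len(self.nodes))
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                p = self.index[node.parent.name]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = node.length
        self.root_index = self.index[tree.root.name]

        k, C = model.k, model.n_categories
        self._leaf_data: dict[int, np.ndarray] = {}
        for leaf in tree.leaves():
            if leaf.name not in aln.records:
                raise PairingError(f"leaf {leaf.name!r} has no sequence")
            seq = aln.records[leaf.name]
            codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            ind = np.zeros((self.n_sites, k))
            for byte in np.unique(codes):
                ch = chr(byte)
                try:
                    comp = compatible_states(ch, model.states)
                except KeyError:
                    raise PairingError(
                        f"character {ch!r} in {leaf.name!r} incompatible with model alphabet"
                    ) from None
                mask = codes == byte
                ind[np.ix_(mask, list(comp))] = 1.0
            self._leaf_data[self.index[leaf.name]] = ind

        self._P: dict[int, np.ndarray] = {}
        self._dirty = True
        # filled by _up_pass
        self._L: list[np.ndarray | None] = [None] * len(self.nodes)
        self._scale: list[np.ndarray | None] = [None] * len(self.nodes)
        self._msg: list[np.ndarray | None] = [None] * len(self.nodes)

    # -- branch lengths ------------------------------------------------
    def set_branch_length(self, node_index: int, t: float) -> None:
        self.lengths[node_index] = t
        self.nodes[node_index].length = t
        self._P.pop(node_index, None)
        self._dirty = True

    def _trans(self, node_index: int) -> np.ndarray:
        P = self._P.get(node_index)
        if P is None:
            P = self.model.transition_matrices(self.lengths[node_index])
            self._P[node_index] = P
        return P

    # -- passes ----------------------------------------------------------
    def _up_pass(self) -> None:
        C, k, n = self.model.n_categories, self.model.k, self.n_sites
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                L = np.broadcast_to(self._leaf_data[i], (C, n, k)).copy()
                scale = np.zeros((C, n))
            else:
                L = np.ones((C, n, k))
                scale = np.zeros((C, n))
                for c in self.children[i]:
                    L = L * self._msg[c]
                    scale = scale + self._scale[c]
                norm = L.max(axis=2)
                np.maximum(norm, _TINY, out=norm)
                L = L / norm[:, :, None]
                scale = scale + np.log(norm)
            self._L[i] = L
            self._scale[i] = scale
            if self.parent[i] >= 0:
                P = self._trans(i)  # (C, k, k)
                self._msg[i] = np.matmul(L, P.transpose(0, 2, 1))
        self._dirty = False

    def _site_category_loglik(self) -> np.ndarray:
        """(C, n_sites) log site likelihoods per rate category."""
        if self._dirty:
            self._up_pass()
        r = self.root_index
        lik = self._L[r] @ self.model.pi  # (C, n_sites)
        return np.log(np.maximum(lik, _TINY)) + self._scale[r]

    def log_likelihood(self) -> tuple[np.ndarray, float]:
        """Per-site log-likelihood vector and its total."""
        percat = self._site_category_loglik()
        logw = np.log(self.model.weights)[:, None]
        site_ll = logsumexp(percat + logw, axis=0)
        return site_ll, float(site_ll.sum())

    # -- marginal ancestral reconstruction -------------------------------
    def ancestral_states(self) -> AncestralReconstruction:
        if self._dirty:
            self._up_pass()
        C, k, n = self.model.n_categories, self.model.k, self.n_sites
        percat = self._site_category_loglik()
        logw = np.log(self.model.weights)[:, None]
        site_ll = logsumexp(percat + logw, axis=0)
        # per-site posterior category weights
        cat_w = np.exp(percat + logw - site_ll[None, :])  # (C, n)

        # outside pass: O[root] = pi
        O: list[np.ndarray | None] = [None] * len(self.nodes)
        O[self.root_index] = np.broadcast_to(
            self.model.pi, (C, n, k)
        ).copy()
        posteriors: dict[str, np.ndarray] = {}
        map_seqs: dict[str, str] = {}
        for u in reversed(range(len(self.nodes))):  # preorder over postorder list
            node = self.nodes[u]
            kids = self.children[u]
            if kids:
                # prefix/suffix products of child messages around each child
                msgs = [self._msg[c] for c in kids]
                for pos, v in enumerate(kids):
                    G = O[u]
                    for q, m in enumerate(msgs):
                        if q != pos:
                            G = G * m
                    Ov = np.matmul(G, self._trans(v))  # (C, n, k)
                    norm = np.maximum(Ov.max(axis=2), _TINY)
                    O[v] = Ov / norm[:, :, None]
            if not node.is_leaf:
                post_c = self._L[u] * O[u]
                tot = np.maximum(post_c.sum(axis=2), _TINY)
                post_c = post_c / tot[:, :, None]
                mixed = np.einsum("cn,cnk->nk", cat_w, post_c)
                mixed = mixed / mixed.sum(axis=1, keepdims=True)
                posteriors[node.name] = mixed
                idx = mixed.argmax(axis=1)  # first max -> lowest alphabet index
                map_seqs[node.name] = "".join(self.model.states[j] for j in idx)
        return AncestralReconstruction(
            states=self.model.states,
            posteriors=posteriors,
            map_sequences=map_seqs,
            site_log_likelihood=site_ll,
            total_log_likelihood=float(site_ll.sum()),
            category_weights=cat_w.T,
        )

    # -- branch-length optimization ---------------------------------------
    def _branch_environment(self, v: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W, L_v, extra_logscale): site likelihood as a function of the
        branch length above v is sum_xy W[x] P_xy(t) L_v[y]."""
        if self._dirty:
            self._up_pass()
        C, k, n = self.model.n_categories, self.model.k, self.n_sites
        # outside message at the top of branch v, via path from root
        path = []
        u = v
        while self.parent[u] >= 0:
            path.append(u)
            u = self.parent[u]
        W = np.broadcast_to(self.model.pi, (C, n, k)).copy()
        extra = np.zeros((C, n))
        for child in reversed(path):
            u = self.parent[child]
            for sib in self.children[u]:
                if sib != child:
                    W = W * self._msg[sib]
                    extra = extra + self._scale[sib]
            if child != v:
                W = np.matmul(W, self._trans(child))
            norm = np.maximum(W.max(axis=2), _TINY)
            W = W / norm[:, :, None]
            extra = extra + np.log(norm)
        return W, self._L[v], extra + self._scale[v]

    def _branch_loglik_fn(self, v: int):
        W, Lv, extra = self._branch_environment(v)
        logw = np.log(self.model.weights)[:, None]

        def fn(t: float) -> float:
            P = self.model.transition_matrices(t)
            s = (np.matmul(W, P) * Lv).sum(axis=2)  # (C, n)
            percat = np.log(np.maximum(s, _TINY)) + extra
            return float(logsumexp(percat + logw, axis=0).sum())

        return fn

    def optimize_branch_lengths(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 50,
        max_length: float = 50.0,
    ) -> tuple[float, bool]:
        """Coordinate-wise branch-length optimization on the fixed topology.

        Sweeps over branches with bounded scalar minimization until the
        total log-likelihood improves by less than ``tol``.  Returns the
        final log-likelihood and a convergence flag.
        """
        _, ll = self.log_likelihood()
        converged = False
        branch_nodes = [i for i in range(len(self.nodes)) if self.parent[i] >= 0]
        for _ in range(max_sweeps):
            for v in branch_nodes:
                fn = self._branch_loglik_fn(v)
                res = minimize_scalar(
                    lambda t: -fn(t),
                    bounds=(0.0, max_length),
                    method="bounded",
                    options={"xatol": 1e-9},
                )
                t_new = float(res.x)
                # keep the better of {current, proposed}; never decrease ll
                if fn(t_new) >= fn(self.lengths[v]):
                    self.set_branch_length(v, t_new)
            _, ll_new = self.log_likelihood()
            if ll_new - ll < tol:
                ll = max(ll, ll_new)
                converged = True
                break
            ll = ll_new
        return ll, converged


# -- module-level conveniences -------------------------------------------

def tree_log_likelihood(
    tree: PhyloTree, model: SubstitutionModel, aln: Alignment
) -> tuple[np.ndarray, float]:
    """Per-site log-likelihoods and total under the pruning algorithm."""
    return TreeLikelihood(tree, model, aln).log_likelihood()


def marginal_ancestral_states(
    tree: PhyloTree, model: SubstitutionModel, aln: Alignment
) -> AncestralReconstruction:
    """Marginal (per-node) ancestral-state posteriors and MAP sequences."""
    return TreeLikelihood(tree, model, aln).ancestral_states()


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, float, bool]:
    """Optimize branch lengths on a fixed topology; returns a new tree.

    The input tree is left untouched.  A non-converged result (after
    ``max_sweeps`` sweeps) is returned with the flag set False rather
    than raised.
    """
    work = tree.copy()
    engine = TreeLikelihood(work, model, aln)
    ll, converged = engine.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)
    return work, ll, converged
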