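"""Reversible continuous-time Markov substitution models.

A model is (exchangeabilities S, stationary frequencies pi, rate-category
mixture).  The generator Q_ij = S_ij * pi_j is rescaled to one expected
substitution per site per unit branch length, and category rates are
normalized to mean 1, so branch lengths read directly in substitutions
per site.  Transition probabilities come from the symmetric
eigendecomposition of the reversible generator, which is exact and cheap
for the 4- and 20-state alphabets used here.

Empirical amino-acid exchangeabilities (JTT, WAG, LG) are shipped as
PAML-format data files; JTT is the default for protein work.  Among-site
rate variation is supplied either as an explicit free-rate list of
(rate, weight) categories or as a discretized gamma (mean-of-quantile
bins).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alphabets import AA_STATES, NT_STATES, compatible_states
from .seqio import Alignment

EMPIRICAL_FILES = {"JTT": "jones.dat", "WAG": "wag.dat", "LG": "lg.dat"}


class ModelSpecError(ValueError):
    """Raised when a model specification violates its invariants."""


def read_paml_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML .dat file: lower-triangle exchangeabilities + frequencies."""
    tokens = Path(path).read_text().split()
    vals = [float(t) for t in tokens]
    if len(vals) < 210:
        raise ModelSpecError(f"short PAML matrix file {path}")
    S = np.zeros((20, 20))
    idx = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = vals[idx]
            idx += 1
    freqs = np.array(vals[idx : idx + 20])
    return S, freqs


def load_empirical(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Load a shipped empirical amino-acid matrix (JTT, WAG or LG)."""
    try:
        fname = EMPIRICAL_FILES[name.upper()]
    except KeyError:
        raise ModelSpecError(f"unknown empirical matrix {name!r}") from None
    ref = resources.files("photoevol.data") / fname
    with resources.as_file(ref) as path:
        return read_paml_matrix(path)


def discretize_gamma(alpha: float, n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-of-quantile discretization of a mean-1 gamma into equal-weight bins.

    With shape ``alpha`` and rate ``alpha`` (mean 1), category c spans the
    quantile interval [c/n, (c+1)/n] and takes the conditional mean of
    the distribution on that interval, so the category mean is exactly 1.
    """
    if alpha <= 0 or n_categories < 1:
        raise ModelSpecError("gamma shape and category count must be positive")
    cuts = gamma_dist.ppf(np.linspace(0, 1, n_categories + 1), alpha, scale=1 / alpha)
    # E[X; X <= c] for Gamma(alpha, rate alpha) is P(alpha+1, alpha*c)
    partial = gammainc(alpha + 1, alpha * cuts)
    partial[0], partial[-1] = 0.0, 1.0
    rates = n_categories * np.diff(partial)
    weights = np.full(n_categories, 1.0 / n_categories)
    return rates, weights


def empirical_frequencies(aln: Alignment, states: str) -> np.ndarray:
    """'+F' frequencies: normalized state counts over non-gap characters.

    Ambiguity codes contribute fractionally over their compatible states.
    """
    counts = np.zeros(len(states))
    for seq in aln.records.values():
        for ch in seq:
            if ch == "-" or ch == "." or ch == "?":
                continue
            comp = list(compatible_states(ch, states))
            counts[comp] += 1.0 / len(comp)
    if counts.sum() == 0:
        raise ModelSpecError("alignment contains no concrete states")
    freqs = counts / counts.sum()
    # guard zero frequencies (absent states) with a small floor
    floor = 1e-6
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


class SubstitutionModel:
    """Reversible CTMC with a rate-category mixture.

    Parameters
    ----------
    exchangeabilities : symmetric non-negative (k, k) array, zero diagonal
    frequencies : length-k stationary distribution, strictly positive
    rates, weights : rate-category mixture; normalized so the weighted
        mean rate is 1
    """

    def __init__(
        self,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        rates: np.ndarray | list[float] | None = None,
        weights: np.ndarray | list[float] | None = None,
        name: str = "custom",
        states: str | None = None,
    ):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        k = pi.size
        if S.shape != (k, k):
            raise ModelSpecError("exchangeability matrix shape mismatch")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ModelSpecError("exchangeability matrix not symmetric")
        if np.any(S < 0) or np.any(np.abs(np.diag(S)) > 1e-12):
            raise ModelSpecError("exchangeabilities must be non-negative, zero diagonal")
        if np.any(pi <= 0):
            raise ModelSpecError("stationary frequencies must be strictly positive")
        if abs(pi.sum() - 1) > 1e-8:
            raise ModelSpecError(f"frequencies sum to {pi.sum()}, not 1")
        pi = pi / pi.sum()

        if rates is None:
            rates, weights = np.array([1.0]), np.array([1.0])
        rates = np.asarray(rates, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if rates.shape != weights.shape or rates.ndim != 1:
            raise ModelSpecError("rates and weights must be equal-length vectors")
        if np.any(rates < 0) or np.any(weights <= 0):
            raise ModelSpecError("rates must be >= 0 and weights > 0")
        weights = weights / weights.sum()
        mean_rate = float(weights @ rates)
        if mean_rate <= 0:
            raise ModelSpecError("mean category rate must be positive")
        rates = rates / mean_rate

        if states is None:
            states = {4: NT_STATES, 20: AA_STATES}.get(k)
            if states is None:
                raise ModelSpecError(f"no default state order for k={k}")

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(pi @ np.diag(Q))
        if scale <= 0:
            raise ModelSpecError("degenerate generator (zero total rate)")
        Q /= scale

        self.states = states
        self.k = k
        self.S = S
        self.pi = pi
        self.Q = Q
        self.rates = rates
        self.weights = weights
        self.name = name

        # symmetric eigendecomposition of the reversible generator
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]        # D^{-1/2} V
        self._right = eigvec.T * sq[None, :]     # V^T D^{1/2}
        self._P_cache: dict[float, np.ndarray] = {}

    @property
    def n_categories(self) -> int:
        return self.rates.size

    def transition_matrix(self, t: float, category: int = 0) -> np.ndarray:
        """P(t) = exp(Q * r_c * t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        r = self.rates[category]
        P = (self._left * np.exp(self._eigval * r * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stacked (n_categories, k, k) transition matrices for one branch.

        Results are cached per branch length (read-only views), since
        likelihood passes and null-simulation replicates revisit the
        same branch lengths many times.
        """
        P = self._P_cache.get(t)
        if P is None:
            P = np.stack(
                [self.transition_matrix(t, c) for c in range(self.n_categories)]
            )
            P.setflags(write=False)
            if len(self._P_cache) < 4096:
                self._P_cache[t] = P
        return P

    # -- constructors --------------------------------------------------
    @classmethod
    def equal_rates(cls, k: int = 20, rates=None, weights=None) -> "SubstitutionModel":
        """The k-state equal-exchangeability, equal-frequency model (EQU)."""
        S = np.ones((k, k)) - np.eye(k)
        pi = np.full(k, 1.0 / k)
        return cls(S, pi, rates, weights, name="EQU")

    @classmethod
    def empirical(
        cls,
        name: str = "JTT",
        frequencies: np.ndarray | None = None,
        alignment: Alignment | None = None,
        gamma_alpha: float | None = None,
        n_categories: int = 1,
        rates=None,
        weights=None,
    ) -> "SubstitutionModel":
        """Build e.g. JTT, JTT+F, JTT+F+G4 or a free-rate variant.

        ``alignment`` triggers '+F' frequencies counted from the data;
        otherwise the matrix's own published frequencies are used unless
        explicit ``frequencies`` are given.  ``gamma_alpha`` requests a
        discretized gamma with ``n_categories`` bins; explicit
        ``rates``/``weights`` express a free-rate mixture instead.
        """
        S, file_freqs = load_empirical(name)
        tag = name.upper()
        if alignment is not None:
            pi = empirical_frequencies(alignment, AA_STATES)
            tag += "+F"
        elif frequencies is not None:
            pi = np.asarray(frequencies, dtype=float)
        else:
            pi = file_freqs / file_freqs.sum()
        if gamma_alpha is not None:
            rates, weights = discretize_gamma(gamma_alpha, n_categories)
            tag += f"+G{n_categories}"
        elif rates is not None:
            tag += f"+R{len(rates)}"
        return cls(S, pi, rates, weights, name=tag)

    @classmethod
    def gtr(
        cls,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        gamma_alpha: float | None = None,
        n_categories: int = 1,
        rates=None,
        weights=None,
    ) -> "SubstitutionModel":
        """General time-reversible nucleotide model from explicit parameters."""
        if gamma_alpha is not None:
            rates, weights = discretize_gamma(gamma_alpha, n_categories)
        return cls(
            np.asarray(exchangeabilities, float),
            np.asarray(frequencies, float),
            rates,
            weights,
            name="GTR",
        )
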