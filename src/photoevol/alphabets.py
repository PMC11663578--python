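"""State alphabets, ambiguity conventions and the genetic code.

Amino acids follow the PAML ordering (ARNDCQEGHILKMFPSTWYV) so that the
empirical exchangeability data files can be read without reindexing.
Gaps ('-') and ambiguity codes are treated as missing data in likelihood
computations: they contribute a partial likelihood of 1 over every
compatible state.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NT_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

GAP = "-"

# IUPAC nucleotide ambiguity -> compatible states
NT_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "U": "T",
}

# Amino-acid ambiguity codes
AA_AMBIGUITY = {
    "B": "ND", "Z": "QE", "J": "IL", "X": AA_STATES,
}


@lru_cache(maxsize=None)
def state_index(alphabet: str) -> dict[str, int]:
    """Map each concrete state character to its index."""
    return {s: i for i, s in enumerate(alphabet)}


@lru_cache(maxsize=None)
def compatible_states(char: str, alphabet: str) -> tuple[int, ...]:
    """Indices of states compatible with ``char`` (empty meaning 'all').

    Concrete states map to themselves; gaps and ambiguity codes map to
    every compatible state.  Raises ``KeyError`` for characters that are
    neither states nor recognized ambiguity/gap codes.
    """
    char = char.upper()
    idx = state_index(alphabet)
    if char in idx:
        return (idx[char],)
    if char == GAP or char == "." or char == "?":
        return tuple(range(len(alphabet)))
    amb = NT_AMBIGUITY if alphabet == NT_STATES else AA_AMBIGUITY
    if char in amb:
        return tuple(idx[s] for s in amb[char])
    raise KeyError(char)


class GeneticCode:
    """A 64-codon translation table.

    Defaults to NCBI translation table 11 (bacterial/archaeal/plant
    plastid), the code used by plastid protein-coding genes.  Stops are
    represented as ``*``.
    """

    def __init__(self, table_id: int = 11):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self._map: dict[str, str] = dict(table.forward_table)
        for codon in table.stop_codons:
            self._map[codon] = "*"
        if len(self._map) != 64:
            raise ValueError(f"incomplete codon table {table_id}")

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        if len(codon) != 3 or any(c not in "ACGT" for c in codon):
            raise ValueError(f"not a concrete codon: {codon!r}")
        return self._map[codon]

    def translate(self, seq: str) -> str:
        if len(seq) % 3:
            raise ValueError("sequence length not a multiple of 3")
        return "".join(
            self.translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)
        )

    def is_stop(self, codon: str) -> bool:
        return self.translate_codon(codon) == "*"
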