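"""Alignment container and FASTA input/output.

The :class:`Alignment` is a thin ordered mapping from sequence id to a
row of states; FASTA parsing is delegated to Biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import AA_AMBIGUITY, AA_STATES, GAP, NT_AMBIGUITY, NT_STATES

ALPHABETS = ("nucleotide", "amino-acid", "codon")


class AlignmentError(ValueError):
    """Raised for ragged alignments, bad characters or empty content."""


def _legal_chars(alphabet: str) -> set[str]:
    if alphabet == "amino-acid":
        chars = set(AA_STATES) | set(AA_AMBIGUITY) | {"*"}
    else:
        chars = set(NT_STATES) | set(NT_AMBIGUITY)
    return chars | {GAP, ".", "?"}


@dataclass
class Alignment:
    """Ordered id -> row mapping over a declared alphabet.

    ``n_sites`` counts columns; for codon alignments a site is a codon
    (the stored strings are still nucleotide characters, length 3x).
    """

    records: dict[str, str]
    alphabet: str = "amino-acid"

    def __post_init__(self):
        if self.alphabet not in ALPHABETS:
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        (length,) = lengths
        if length == 0:
            raise AlignmentError("alignment has zero columns")
        if self.alphabet == "codon" and length % 3:
            raise AlignmentError("codon alignment length not a multiple of 3")
        legal = _legal_chars(self.alphabet)
        for rid, seq in self.records.items():
            seq = seq.upper()
            self.records[rid] = seq
            for col, ch in enumerate(seq, start=1):
                if ch not in legal:
                    raise AlignmentError(
                        f"illegal character {ch!r} in record {rid!r} at column {col}"
                    )

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_sites(self) -> int:
        length = len(next(iter(self.records.values())))
        return length // 3 if self.alphabet == "codon" else length

    def column(self, i: int) -> str:
        """Column ``i`` (0-based character column) across records."""
        return "".join(seq[i] for seq in self.records.values())

    def __len__(self) -> int:
        return len(self.records)


def read_fasta_alignment(path: str | Path | io.TextIOBase, alphabet: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order is preserved.  Raises :class:`AlignmentError` on ragged
    rows, duplicate ids or characters outside the declared alphabet.
    """
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        records: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise AlignmentError(f"duplicate sequence id {rec.id!r}")
            records[rec.id] = str(rec.seq)
    finally:
        if handle is not path:
            handle.close()
    if not records:
        raise AlignmentError("no FASTA records found")
    return Alignment(records, alphabet)


def write_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def trim_gap_columns(
    aln: Alignment, max_gap_frac: float = 0.9
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_frac``.

    Returns the trimmed alignment plus a column map giving, for each kept
    column, its original 1-based index.  The 0.9 default drops columns
    with >90% gaps.  Codon alignments are trimmed codon-wise (a codon
    column is gapped in a record when any of its three characters is a
    gap in that record).
    """
    if not (0 < max_gap_frac <= 1):
        raise ValueError("max_gap_frac must be in (0, 1]")
    n = aln.n_sequences
    step = 3 if aln.alphabet == "codon" else 1
    keep: list[int] = []
    for site in range(aln.n_sites):
        cols = [aln.column(site * step + j) for j in range(step)]
        gapped = sum(
            1 for r in range(n) if any(col[r] == GAP for col in cols)
        )
        if gapped / n <= max_gap_frac:
            keep.append(site)
    if not keep:
        raise AlignmentError("all columns removed by gap trimming")
    records = {
        rid: "".join(seq[s * step : s * step + step] for s in keep)
        for rid, seq in aln.records.items()
    }
    return Alignment(records, aln.alphabet), [s + 1 for s in keep]
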