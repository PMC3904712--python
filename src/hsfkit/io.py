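"""Validated FASTA input/output.

Thin wrappers over :mod:`Bio.SeqIO` that add the error contract the rest of
the toolkit relies on: a missing header line, an empty sequence, duplicated
record identifiers and residues outside the declared alphabet are each
reported as a distinct :class:`FastaError`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO

__all__ = ["SequenceRecord", "FastaError", "read_fasta", "write_fasta"]

# IUPAC alphabets.  DNA includes ambiguity codes; protein includes X.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class FastaError(ValueError):
    """Raised on malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence with a declared alphabet ('dna' or 'protein')."""

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def _validate(record: SequenceRecord, index: int) -> None:
    if not record.residues:
        raise FastaError(f"record {record.id!r} (#{index}) has an empty sequence")
    allowed = DNA_ALPHABET if record.alphabet == "dna" else PROTEIN_ALPHABET
    bad = set(record.residues) - allowed
    if bad:
        raise FastaError(
            f"record {record.id!r} contains residues outside the "
            f"{record.alphabet} alphabet: {sorted(bad)}"
        )


def read_fasta(source: Union[str, Path, TextIO], alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA stream or path into validated records.

    Residues are uppercased; input order is preserved.  Raises
    :class:`FastaError` for an empty file, text before the first header,
    an empty sequence, duplicate ids or out-of-alphabet residues.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    stripped = text.lstrip()
    if not stripped:
        raise FastaError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FastaError("missing header: FASTA input must start with '>'")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(_io.StringIO(text), "fasta")):
        if rec.id in seen:
            raise FastaError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)
        out = SequenceRecord(
            id=rec.id,
            residues=str(rec.seq).upper(),
            alphabet=alphabet,
            description=rec.description,
        )
        _validate(out, i)
        records.append(out)
    if not records:
        raise FastaError("no records in FASTA input")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: Union[str, Path, TextIO], width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w") if own else dest
    try:
        for rec in records:
            header = rec.description if rec.description and rec.description != rec.id else rec.id
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    finally:
        if own:
            handle.close()
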