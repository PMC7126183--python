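"""FASTA I/O, synthetic plasmid fixtures, and core sequence utilities.

Sequences live on the uppercase alphabet ``{A, C, G, T, N}``. Plasmids
are physically circular molecules, but FASTA cannot express topology, so
circularity is an explicit flag on :class:`SequenceRecord` (default
``False``) set by the caller, the CLI or a config file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (e.g. content before the first '>')."""


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def _validate_alphabet(sequence: str, name: str = "sequence") -> None:
    bad = set(sequence) - ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"{name} contains characters outside {{A,C,G,T,N}}: "
            f"{sorted(bad)!r}"
        )


@dataclass
class SequenceRecord:
    """A named DNA sequence with a circularity flag.

    Parameters
    ----------
    id : str
        Non-empty identifier without whitespace (the first token of a
        FASTA header).
    sequence : str
        Uppercase DNA over ``{A,C,G,T,N}``. Lowercase input is
        normalised to uppercase.
    circular : bool
        Whether the molecule is topologically circular. Plasmids are;
        the default is ``False`` because the simulation pipeline
        operates on the linear string unless told otherwise.
    description : str
        Remainder of the FASTA header after the id; carried through I/O
        but ignored by analyses.
    """

    id: str
    sequence: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"record id must be non-empty without whitespace, got {self.id!r}")
        self.sequence = self.sequence.upper()
        _validate_alphabet(self.sequence, name=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_fasta(source) -> list[SequenceRecord]:
    """Parse FASTA text (a string or a text file handle) into records.

    Header lines start with ``>``; the id is the first
    whitespace-delimited token and the remainder of the header is kept
    as ``description``. Sequence lines may wrap arbitrarily and are
    concatenated with whitespace stripped; lowercase is uppercased.
    Record order is preserved.

    Raises
    ------
    FastaFormatError
        If non-whitespace content precedes the first ``>`` header.
    InvalidAlphabetError
        If a record contains characters outside ``{A,C,G,T,N}``,
        naming the offending record.
    """
    if isinstance(source, str):
        text = source
    else:
        text = source.read()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaFormatError("FASTA content found before the first '>' header")
    records = []
    with io.StringIO(text) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise FastaFormatError("FASTA header with empty id")
            rec_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            records.append(SequenceRecord(id=rec_id, sequence=seq, description=description))
    return records


def write_fasta(records, wrap: int = 70) -> str:
    """Render records as FASTA text with sequence lines of width ``wrap``.

    ``parse_fasta(write_fasta(records))`` reproduces ids, descriptions
    and sequences.
    """
    if wrap < 1:
        raise ValueError(f"wrap must be >= 1, got {wrap}")
    chunks: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        chunks.append(header + "\n")
        seq = rec.sequence
        for i in range(0, len(seq), wrap):
            chunks.append(seq[i : i + wrap] + "\n")
    return "".join(chunks)


def random_plasmid(length: int, gc_fraction: float, seed: int, circular: bool = False) -> SequenceRecord:
    """Generate a random plasmid-like template with a target GC fraction.

    Each base is drawn independently with ``P(G) = P(C) =
    gc_fraction/2`` and ``P(A) = P(T) = (1 - gc_fraction)/2``. The same
    ``(length, gc_fraction, seed)`` always yields the same sequence.
    Realistic cloning-vector compositions sit around 40-60% GC.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])
    gc_tag = f"{gc_fraction:.3f}".replace(".", "")
    return SequenceRecord(
        id=f"synth_{length}bp_gc{gc_tag}_s{seed}",
        sequence="".join(bases),
        circular=circular,
        description=f"synthetic random plasmid length={length} gc={gc_fraction} seed={seed}",
    )


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a DNA string (N maps to N); an involution."""
    sequence = sequence.upper()
    _validate_alphabet(sequence)
    return sequence.translate(_COMPLEMENT)[::-1]
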