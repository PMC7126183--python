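"""Error-free Sanger-style shotgun read simulation.

Reads of a fixed length L are drawn from a template of length G until
the total number of sequenced bases divided by G reaches the requested
coverage c, i.e. exactly ``ceil(c*G/L)`` reads. Start positions are
uniform — over ``[0, G-L]`` in linear mode, over ``[0, G)`` with
wraparound through the origin in circular mode — and each read is
independently assigned the reverse strand with probability
``reverse_fraction``. Reads carry no base-calling errors: the Sanger
chemistry being emulated is highly accurate, and downstream identity
thresholds already leave room for a future substitution model.

Reproducibility contract: one ``numpy.random.default_rng(seed)`` stream
is consumed in a fixed order — for each read in turn, first the start
(``rng.integers``), then the strand (``rng.random`` compared against
``reverse_fraction``). Read ids are ``r{index}`` in generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from plasmidshot.seqio import SequenceRecord, reverse_complement


@dataclass
class SimulationParams:
    """Shotgun simulation settings.

    read_length
        Exact read length L in nucleotides (Sanger reads top out around
        800 nt, the default).
    coverage
        Target coverage c >= 0: total sequenced bases / template length.
    reverse_fraction
        Probability that a read is reported from the reverse strand
        (default 0.5 — both strands are sequenced).
    circular
        Draw starts over the whole circle with wraparound instead of
        over ``[0, G-L]``.
    seed
        RNG seed; identical seeds give identical read sets.
    """

    read_length: int = 800
    coverage: float = 1.0
    reverse_fraction: float = 0.5
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if not 0.0 <= self.reverse_fraction <= 1.0:
            raise ValueError(f"reverse_fraction must be in [0, 1], got {self.reverse_fraction}")


@dataclass
class Read:
    """One simulated read.

    ``start`` is the 0-based template offset of the leftmost template
    base covered (reads from the reverse strand still record their
    leftmost template coordinate). In circular mode the covered
    interval may wrap through the origin.
    """

    id: str
    sequence: str
    start: int
    strand: str  # '+' or '-'
    length: int


@dataclass
class ReadSet:
    """All reads simulated from one template."""

    reads: list[Read]
    template_id: str
    template_length: int
    total_bases: int
    read_length: int
    circular: bool = False

    def __len__(self) -> int:
        return len(self.reads)


def required_read_count(template_length: int, read_length: int, coverage: float) -> int:
    """Smallest N with ``N*read_length >= coverage*template_length``.

    This is the simulator's stopping rule: reads are emitted until the
    sequenced-bases / template-length ratio reaches the coverage
    threshold.
    """
    if template_length < 1:
        raise ValueError(f"template_length must be >= 1, got {template_length}")
    if read_length < 1:
        raise ValueError(f"read_length must be >= 1, got {read_length}")
    if coverage < 0:
        raise ValueError(f"coverage must be >= 0, got {coverage}")
    if coverage == 0:
        return 0
    return math.ceil(coverage * template_length / read_length)


def simulate_reads(template: SequenceRecord, params: SimulationParams) -> ReadSet:
    """Simulate an error-free shotgun read set from ``template``.

    Raises
    ------
    ValueError
        If ``read_length`` exceeds the template length.
    """
    G = len(template.sequence)
    L = params.read_length
    if G < 1:
        raise ValueError("template must be non-empty")
    if L > G:
        raise ValueError(f"read_length {L} exceeds template length {G}")
    n_reads = required_read_count(G, L, params.coverage)
    rng = np.random.default_rng(params.seed)
    seq = template.sequence
    doubled = seq + seq  # wraparound slices in circular mode
    reads: list[Read] = []
    for i in range(n_reads):
        if params.circular:
            start = int(rng.integers(0, G))
        else:
            start = int(rng.integers(0, G - L + 1))
        is_reverse = bool(rng.random() < params.reverse_fraction)
        fragment = doubled[start : start + L] if params.circular else seq[start : start + L]
        reads.append(
            Read(
                id=f"r{i}",
                sequence=reverse_complement(fragment) if is_reverse else fragment,
                start=start,
                strand="-" if is_reverse else "+",
                length=L,
            )
        )
    return ReadSet(
        reads=reads,
        template_id=template.id,
        template_length=G,
        total_bases=n_reads * L,
        read_length=L,
        circular=params.circular,
    )


def reads_to_fasta_records(readset: ReadSet) -> list[SequenceRecord]:
    """Render reads as FASTA records; headers carry the true start and
    strand (``r12 start=345 strand=-``) for oracle use only — the
    assembler never reads them."""
    return [
        SequenceRecord(
            id=read.id,
            sequence=read.sequence,
            description=f"start={read.start} strand={read.strand}",
        )
        for read in readset.reads
    ]
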