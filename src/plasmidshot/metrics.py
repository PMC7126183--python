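"""Composition, molecular weight, identity, copy number and topology.

These are the evaluation metrics applied to a reference template and
its reassembled counterpart: GC/AT content, single-stranded DNA
molecular weight, end-to-end alignment identity, the PCR copy-number
formula, and a diagnosis of the "impaired topology" artifact — an
assembly of a circular molecule whose missing reference prefix
reappears, reverse-complemented, at the end of the assembled sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from plasmidshot.seqio import SequenceRecord, reverse_complement
from plasmidshot.karlin import ScoringScheme, find_msp

AVOGADRO = 6.02214076e23

# Single-stranded DNA residue masses (Da per incorporated nucleotide
# monophosphate) plus a terminal adjustment for the free ends. These
# are the conventional average masses; tools differ in their rounding
# conventions, so the constants are arguments, not burned in.
DEFAULT_RESIDUE_MASSES = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
DEFAULT_TERMINAL_MASS = 79.0


@dataclass
class CompositionReport:
    """GC/AT percentages and ssDNA molecular weight.

    N bases are excluded from the percentage denominator and from the
    mass sum; ``length`` is the full sequence length including N.
    """

    gc_percent: float
    at_percent: float
    mw_kda: float
    length: int


@dataclass
class IdentityResult:
    """Identity over all columns of an optimal global alignment."""

    identity: float
    alignment_length: int
    matches: int


@dataclass
class TopologyReport:
    """Classification of assembled-vs-reference sequence topology.

    classification
        ``exact`` — sequences are equal; ``rotation`` — the assembled
        sequence is a circular rotation of the reference; ``impaired``
        — the reference prefix missing from the shared region matches
        the reverse complement of the assembled sequence's trailing
        overhang; ``mismatch`` — none of the above.
    """

    classification: str
    uncovered_ref_prefix: int
    uncovered_asm_suffix: int
    evidence_identity: float


def composition(
    sequence: str,
    residue_masses: dict[str, float] | None = None,
    terminal_mass: float = DEFAULT_TERMINAL_MASS,
) -> CompositionReport:
    """GC%, AT% and single-stranded molecular weight of a DNA string."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    masses = residue_masses or DEFAULT_RESIDUE_MASSES
    counts = {base: sequence.count(base) for base in "ACGT"}
    acgt = sum(counts.values())
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    gc = counts["G"] + counts["C"]
    mw = sum(counts[base] * masses[base] for base in "ACGT") + terminal_mass
    return CompositionReport(
        gc_percent=100.0 * gc / acgt,
        at_percent=100.0 * (acgt - gc) / acgt,
        mw_kda=mw / 1000.0,
        length=len(sequence),
    )


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> IdentityResult:
    """Identity of an optimal end-to-end (Needleman-Wunsch) alignment.

    Identity is ``matches / alignment_length`` counted over *all*
    alignment columns, gapped columns included, so missing or rearranged
    sequence is penalised. Symmetric in its arguments; equals 1 iff
    the sequences are equal. When exactly one sequence is empty the
    identity is 0 over the other's length.
    """
    a = a.upper()
    b = b.upper()
    if not a and not b:
        raise ValueError("both sequences are empty")
    if not a or not b:
        other = a or b
        return IdentityResult(identity=0.0, alignment_length=len(other), matches=0)
    aligner = _make_aligner(match, mismatch, gap)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    matches = sum(x == y for x, y in zip(aligned_a, aligned_b))
    columns = len(aligned_a)
    return IdentityResult(identity=matches / columns, alignment_length=columns, matches=matches)


def copy_number(mass_ng: float, length_nt: int, avogadro: float = AVOGADRO) -> float:
    """DNA copies in ``mass_ng`` nanograms of fragments of ``length_nt``:
    ``(mass_ng * N_A) / (length_nt * 650e9)``, with 650 Da the average
    mass per base pair."""
    if mass_ng < 0:
        raise ValueError(f"mass_ng must be >= 0, got {mass_ng}")
    if length_nt < 1:
        raise ValueError(f"length_nt must be >= 1, got {length_nt}")
    return (mass_ng * avogadro) / (length_nt * 650.0 * 1e9)


def diagnose_topology(
    reference: SequenceRecord,
    assembled: SequenceRecord,
    min_block: int = 50,
    min_evidence_identity: float = 0.9,
) -> TopologyReport:
    """Classify an assembled sequence against its reference.

    Linearising a circular template before shotgun simulation produces
    assemblies that start partway around the circle; a greedy
    assembler can additionally emit the pre-start stretch
    reverse-complemented at the contig's end ("impaired topology").
    The shared region is anchored on the maximal-scoring ungapped
    segment between the two sequences; the reference prefix and the
    assembled suffix left outside that anchored diagonal are compared
    (reverse-complemented) by global alignment.
    """
    ref = reference.sequence
    asm = assembled.sequence
    if not ref or not asm:
        raise ValueError("reference and assembled sequences must be non-empty")
    if ref == asm:
        return TopologyReport("exact", 0, 0, 1.0)
    if len(ref) == len(asm) and asm in ref + ref:
        return TopologyReport("rotation", 0, 0, 1.0)

    msp = find_msp(ref, asm, ScoringScheme.from_sequences(ref, asm))
    if msp.orientation == "+":
        # extend the MSP diagonal to the sequence bounds
        offset = msp.a_start - msp.b_start  # ref position aligned to asm position 0
        uncovered_ref_prefix = max(offset, 0)
        uncovered_asm_suffix = max(len(asm) - (len(ref) - offset), 0)
    else:
        uncovered_ref_prefix = 0
        uncovered_asm_suffix = 0
    evidence = 0.0
    if uncovered_ref_prefix >= min_block and uncovered_asm_suffix >= min_block:
        block_ref = ref[:uncovered_ref_prefix]
        block_asm = reverse_complement(asm[len(asm) - uncovered_asm_suffix :])
        evidence = global_identity(block_ref, block_asm).identity
        if evidence >= min_evidence_identity:
            return TopologyReport("impaired", uncovered_ref_prefix, uncovered_asm_suffix, evidence)
    return TopologyReport("mismatch", uncovered_ref_prefix, uncovered_asm_suffix, evidence)
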