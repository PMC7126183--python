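"""Greedy overlap-layout-consensus assembly of shotgun reads.

The assembler follows the classic greedy strategy of early
whole-genome assemblers: score all pairwise suffix-prefix overlaps
(both orientations), repeatedly merge the pair with the longest
passing overlap, recompute overlaps involving the merged contig, and
stop when no pair passes the ``min_overlap`` / ``min_identity``
thresholds. Ties are broken deterministically: fewer mismatches, then
the lexicographically smallest ordered id pair, then forward before
reverse orientation.

Overlap detection is ungapped. Because any overlap of length ``k``
with at most ``m = floor(k*(1-min_identity))`` mismatches must contain
an exact run of at least ``ceil((k-m)/(m+1))`` bases (pigeonhole),
candidate pairs are restricted to sequences sharing an exact seed
k-mer of that guaranteed length — a lossless seed-and-extend filter
that keeps the all-pairs stage near-linear in practice for error-free
reads.

Consensus: merges are pairwise, so every merged column holds two
bases; a 2-way majority is always a tie and the rule "ties resolve
toward the earlier-merged sequence's base" reduces to keeping the
earlier sequence verbatim across the overlap (merged = a + b[k:]).

``island_count_oracle`` is an independent layout-based oracle: it uses
the *true* read coordinates (known to the simulator) to count
connected components of reads whose template intervals overlap by at
least ``min_overlap`` — the theory-level contig count against which
the sequence-level assembler is validated.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from plasmidshot.seqio import reverse_complement
from plasmidshot.simulator import ReadSet


@dataclass
class AssemblyParams:
    """Greedy-assembler thresholds.

    min_overlap
        Minimum suffix-prefix overlap length T in nt (default 40,
        classic shotgun practice).
    min_identity
        Minimum overlap identity (default 0.95; error-free reads
        always satisfy it, the slack anticipates substitution errors).
    consider_reverse
        Also test overlaps against reverse-complemented partners.
    seed
        Reserved for tie-breaking shuffles; unused by the default
        deterministic tie-break.
    """

    min_overlap: int = 40
    min_identity: float = 0.95
    consider_reverse: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError(f"min_overlap must be >= 1, got {self.min_overlap}")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError(f"min_identity must be in (0, 1], got {self.min_identity}")


@dataclass
class Overlap:
    """An accepted suffix(a)/prefix(b) ungapped overlap."""

    a_id: str
    b_id: str
    length: int
    mismatches: int
    orientation: str  # 'forward' or 'reverse'


@dataclass
class Contig:
    """A consensus sequence with the layout of its constituent reads.

    Each layout entry ``(read_id, offset, strand)`` places a read at a
    0-based contig offset; a '-' strand read matches the contig after
    reverse complementation.
    """

    id: str
    sequence: str
    layout: list[tuple[str, int, str]]


@dataclass
class Assembly:
    contigs: list[Contig]
    n_contigs: int
    unplaced: list[str] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_budget(k: int, min_identity: float) -> float:
    return k * (1.0 - min_identity) + 1e-9


def _longest_overlap(a_arr: np.ndarray, b_arr: np.ndarray, min_overlap: int, min_identity: float):
    """Longest k with suffix(a, k) matching prefix(b, k) within the
    identity budget; returns (k, mismatches) or None."""
    la = len(a_arr)
    kmax = min(la, len(b_arr))
    for k in range(kmax, min_overlap - 1, -1):
        mism = int(np.count_nonzero(a_arr[la - k :] != b_arr[:k]))
        if mism <= _mismatch_budget(k, min_identity):
            return k, mism
    return None


def suffix_prefix_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> Overlap | None:
    """Longest suffix-of-``a`` / prefix-of-``b`` ungapped overlap with
    ``length >= min_overlap`` and identity ``>= min_identity``, or
    ``None`` (also for empty inputs)."""
    if not a or not b:
        return None
    hit = _longest_overlap(_encode(a), _encode(b), min_overlap, min_identity)
    if hit is None:
        return None
    k, mism = hit
    return Overlap(a_id="a", b_id="b", length=k, mismatches=mism, orientation="forward")


def _seed_length(min_overlap: int, min_identity: float) -> int:
    """Guaranteed exact-match run length inside any passing overlap.

    Minimises ceil((k-m)/(m+1)) over overlap lengths k; shorter (more
    permissive) seeds are always safe, so the asymptotic bound is
    folded in and the result capped at 32.
    """
    q = 1.0 - min_identity
    best = min_overlap
    for k in range(min_overlap, min_overlap + 1000):
        m = int(math.floor(k * q + 1e-9))
        best = min(best, math.ceil((k - m) / (m + 1)))
    if q > 0:
        best = min(best, math.ceil((1.0 - q) / q))
    return max(1, min(best, 32))


class _Item:
    """A live read or contig during greedy merging."""

    __slots__ = ("id", "seq", "arr", "rc_arr", "layout")

    def __init__(self, item_id: str, seq: str, layout: list[tuple[str, int, str, int]]):
        self.id = item_id
        self.seq = seq
        self.arr = _encode(seq)
        self.rc_arr = _encode(reverse_complement(seq))
        self.layout = layout  # (read_id, offset, strand, read_length)

    def flipped_layout(self) -> list[tuple[str, int, str, int]]:
        n = len(self.seq)
        return [
            (rid, n - off - rlen, "-" if strand == "+" else "+", rlen)
            for rid, off, strand, rlen in self.layout
        ]


def _kmers(seq: str, k: int):
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


class _GreedyState:
    def __init__(self, params: AssemblyParams):
        self.params = params
        self.seed_len = _seed_length(params.min_overlap, params.min_identity)
        self.items: dict[str, _Item] = {}
        self.index: dict[str, set[str]] = {}
        self.heap: list = []
        self.merge_counter = 0

    def _index_item(self, item: _Item) -> None:
        for kmer in _kmers(item.seq, self.seed_len):
            self.index.setdefault(kmer, set()).add(item.id)

    def _unindex_item(self, item: _Item) -> None:
        for kmer in _kmers(item.seq, self.seed_len):
            bucket = self.index.get(kmer)
            if bucket is not None:
                bucket.discard(item.id)
                if not bucket:
                    del self.index[kmer]

    def _candidates(self, item: _Item) -> tuple[set[str], set[str]]:
        fwd: set[str] = set()
        for kmer in _kmers(item.seq, self.seed_len):
            fwd |= self.index.get(kmer, set())
        rev: set[str] = set()
        if self.params.consider_reverse:
            for kmer in _kmers(reverse_complement(item.seq), self.seed_len):
                rev |= self.index.get(kmer, set())
        fwd.discard(item.id)
        rev.discard(item.id)
        # sequences too short to carry a seed must be paired with everything
        if len(item.seq) < self.seed_len:
            everyone = set(self.items) - {item.id}
            fwd |= everyone
            if self.params.consider_reverse:
                rev |= everyone
        return fwd, rev

    # merge codes: 0 = lead + trail (forward); 1 = lead + rc(trail);
    # 2 = rc(lead) + trail. Codes 1 and 2 are the two reverse-orientation
    # arrangements; the heap key orders forward merges before reverse
    # ones at equal (length, mismatches, id pair).
    def _push(self, first_id: str, second_id: str, code: int, k: int, mism: int) -> None:
        heapq.heappush(self.heap, (-k, mism, first_id, second_id, code))

    def _score_pair(self, x: _Item, y: _Item, orientation: str) -> None:
        """Evaluate both merge directions for one orientation and queue hits."""
        T, ident = self.params.min_overlap, self.params.min_identity
        if orientation == "forward":
            hit = _longest_overlap(x.arr, y.arr, T, ident)
            if hit:
                self._push(x.id, y.id, 0, *hit)
            hit = _longest_overlap(y.arr, x.arr, T, ident)
            if hit:
                self._push(y.id, x.id, 0, *hit)
        else:
            # x followed by reverse-complemented y ...
            hit = _longest_overlap(x.arr, y.rc_arr, T, ident)
            if hit:
                self._push(x.id, y.id, 1, *hit)
            # ... and reverse-complemented y followed by x
            hit = _longest_overlap(y.rc_arr, x.arr, T, ident)
            if hit:
                self._push(y.id, x.id, 2, *hit)

    def add_item(self, item: _Item) -> None:
        """Register an item, scoring it against previously added live items."""
        fwd, rev = self._candidates(item)
        for other_id in sorted(fwd):
            self._score_pair(item, self.items[other_id], "forward")
        for other_id in sorted(rev):
            self._score_pair(item, self.items[other_id], "reverse")
        self.items[item.id] = item
        self._index_item(item)

    def _merge(self, a: _Item, b: _Item, code: int, k: int) -> _Item:
        """Merge two items overlapping by k columns per the merge code."""
        if code == 0:
            lead_seq, lead_layout = a.seq, list(a.layout)
            trail_seq, trail_layout = b.seq, list(b.layout)
        elif code == 1:
            lead_seq, lead_layout = a.seq, list(a.layout)
            trail_seq, trail_layout = reverse_complement(b.seq), b.flipped_layout()
        else:
            lead_seq, lead_layout = reverse_complement(a.seq), a.flipped_layout()
            trail_seq, trail_layout = b.seq, list(b.layout)
        shift = len(lead_seq) - k
        merged_seq = lead_seq + trail_seq[k:]
        merged_layout = lead_layout + [
            (rid, off + shift, strand, rlen) for rid, off, strand, rlen in trail_layout
        ]
        self.merge_counter += 1
        return _Item(f"m{self.merge_counter}", merged_seq, merged_layout)

    def run(self) -> None:
        while self.heap:
            neg_k, mism, first_id, second_id, code = heapq.heappop(self.heap)
            if first_id not in self.items or second_id not in self.items:
                continue  # stale: a participant was already merged away
            a = self.items.pop(first_id)
            b = self.items.pop(second_id)
            self._unindex_item(a)
            self._unindex_item(b)
            merged = self._merge(a, b, code, -neg_k)
            self.add_item(merged)


def greedy_assemble(reads, params: AssemblyParams | None = None) -> Assembly:
    """Assemble reads into contigs by iterative greedy overlap merging.

    ``reads`` is a :class:`~plasmidshot.simulator.ReadSet` or a list of
    sequences/(id, sequence) pairs. Deterministic given inputs and
    parameters.

    Raises
    ------
    ValueError
        If the read list is empty.
    """
    if params is None:
        params = AssemblyParams()
    if isinstance(reads, ReadSet):
        entries = [(read.id, read.sequence) for read in reads.reads]
    else:
        entries = []
        for i, item in enumerate(reads):
            if isinstance(item, str):
                entries.append((f"r{i}", item))
            else:
                entries.append((item[0], item[1]))
    if not entries:
        raise ValueError("cannot assemble an empty read list")

    state = _GreedyState(params)
    for rid, seq in entries:
        state.add_item(_Item(rid, seq, [(rid, 0, "+", len(seq))]))
    state.run()

    live = sorted(state.items.values(), key=lambda it: (-len(it.seq), it.id))
    contigs = [
        Contig(
            id=f"c{i}",
            sequence=item.seq,
            layout=[(rid, off, strand) for rid, off, strand, _ in item.layout],
        )
        for i, item in enumerate(live)
    ]
    return Assembly(contigs=contigs, n_contigs=len(contigs), unplaced=[])


def island_count_oracle(readset: ReadSet, min_overlap: int) -> int:
    """Count read islands from true coordinates.

    Reads are linked iff their template intervals overlap by at least
    ``min_overlap``; the number of connected components is the
    theoretical contig count for an error-free assembly at threshold
    ``min_overlap``. Circular read sets (uniform read length) are
    scanned on the circle, including the wraparound junction.
    """
    n = len(readset.reads)
    if n == 0:
        return 0
    G = readset.template_length
    if readset.circular:
        L = readset.read_length
        starts = sorted(read.start for read in readset.reads)
        breaks = 0
        for i in range(n):
            gap = (starts[(i + 1) % n] - starts[i]) % G
            if gap > L - min_overlap:
                breaks += 1
        return breaks if breaks > 0 else 1
    intervals = sorted((read.start, read.start + read.length) for read in readset.reads)
    islands = 1
    max_end = intervals[0][1]
    for start, end in intervals[1:]:
        if start > max_end - min_overlap:
            islands += 1
        max_end = max(max_end, end)
    return islands
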