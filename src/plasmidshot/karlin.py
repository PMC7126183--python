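"""Dot-plot comparison and Karlin-Altschul local-alignment statistics.

For an ungapped match/mismatch scoring scheme with negative expected
score and at least one positive score, the score of the
maximal-scoring segment pair (MSP) between two random sequences
follows an extreme-value law governed by two constants: ``lambda``,
the unique positive root of

    sum_ij p_i p_j exp(lambda * s(i, j)) = 1,

and ``K``, a search-space correction. The expected number of chance
MSPs with score at least S between sequences of lengths m and n is

    E = K * m * n * exp(-lambda * S).

``lambda`` is found by bracketed root-finding. ``K`` is computed by
the classical lattice series: scores are rescaled by their gcd ``g``
(segment scores of varying length populate the lattice ``g*Z``), and
with relative entropy ``H = lambda * E[X exp(lambda X)]`` and

    sigma = sum_{k>=1} (1/k) * ( P(S_k >= 0) + E[exp(lambda*S_k); S_k < 0] ),

the constant is ``K = g * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*g)))``.
The series terms decay geometrically (both tail probabilities obey a
large-deviation bound at rate ``min_theta E[exp(theta*X)] < 1``), and
partial K estimates are iterated until successive values differ by
less than the tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from plasmidshot.seqio import reverse_complement

_BASES = "ACGT"
_NEG = -(10**7)


class NoPositiveRootError(ValueError):
    """The normalization equation has no positive root (expected score
    is non-negative, or no positive score exists)."""


class KConvergenceError(RuntimeError):
    """The K series did not converge within the iteration cap."""


@dataclass
class ScoringScheme:
    """Ungapped DNA scoring: +match for identity, mismatch otherwise.

    ``composition`` is the background base-frequency vector over
    (A, C, G, T); it must sum to 1. Default +5/-4 at uniform
    composition — the classical ungapped DNA scheme.
    """

    match: int = 5
    mismatch: int = -4
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or not math.isclose(comp.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("composition must be 4 non-negative frequencies summing to 1")
        self.composition = tuple(float(x) for x in comp)

    @property
    def p_match(self) -> float:
        return float(sum(p * p for p in self.composition))

    @property
    def expected_score(self) -> float:
        q = self.p_match
        return q * self.match + (1.0 - q) * self.mismatch

    @classmethod
    def from_sequences(cls, *sequences: str, match: int = 5, mismatch: int = -4) -> "ScoringScheme":
        """Scheme with composition estimated from the input sequences
        (A/C/G/T counts pooled; falls back to uniform if empty)."""
        counts = np.zeros(4)
        for seq in sequences:
            for i, base in enumerate(_BASES):
                counts[i] += seq.upper().count(base)
        total = counts.sum()
        comp = counts / total if total > 0 else np.full(4, 0.25)
        return cls(match=match, mismatch=mismatch, composition=tuple(comp))


@dataclass
class KarlinParams:
    """The (lambda, K) pair for E-value computation."""

    lambda_: float
    K: float

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lambda_}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")


@dataclass
class MSP:
    """Maximal-scoring segment pair.

    ``a_start``/``b_start`` are 0-based offsets of the segment's
    leftmost base in each sequence (for reverse orientation,
    ``b_start`` is reported on b's forward coordinates).
    """

    score: int
    length: int
    a_start: int
    b_start: int
    orientation: str  # '+' or '-'


@dataclass
class DotPlot:
    """Window pairs scoring at or above the stringency cutoff.

    Each hit is ``(a_pos, b_pos, strand)`` where the positions are the
    starting offsets of the window on each sequence's forward
    coordinates; reverse-strand similarity therefore appears as
    negative-slope diagonals.
    """

    window: int
    cutoff: int
    hits: list[tuple[int, int, str]]
    n_dots: int


def estimate_lambda(scheme: ScoringScheme) -> float:
    """Positive root of the Karlin-Altschul normalization equation,
    solved to absolute tolerance 1e-9 (residual checked in tests).

    Raises
    ------
    NoPositiveRootError
        If the expected score is non-negative or no positive score
        exists — the extreme-value regime then does not apply.
    """
    if scheme.expected_score >= 0:
        raise NoPositiveRootError(
            f"expected per-position score must be negative, got {scheme.expected_score:.4g}"
        )
    if max(scheme.match, scheme.mismatch) <= 0:
        raise NoPositiveRootError("scheme has no positive score")
    q = scheme.p_match

    def f(lam: float) -> float:
        return q * math.exp(lam * scheme.match) + (1.0 - q) * math.exp(lam * scheme.mismatch) - 1.0

    hi = 0.5
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - unreachable for valid schemes
            raise NoPositiveRootError("failed to bracket the positive root")
    lo = 1e-4
    while f(lo) >= 0:
        lo /= 8.0
        if lo < 1e-300:  # pragma: no cover
            raise NoPositiveRootError("failed to bracket the positive root")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _step_distribution(scheme: ScoringScheme) -> tuple[np.ndarray, int, int]:
    """Per-position score distribution, rescaled by the score gcd.

    Segment scores of varying lengths populate the lattice ``g*Z``
    with ``g = gcd`` of the achievable per-position scores, so the
    series works in units of g. Returns (probs, low, g): probability
    of rescaled score ``low + i`` at index i.
    """
    values = {scheme.match: scheme.p_match}
    values[scheme.mismatch] = values.get(scheme.mismatch, 0.0) + (1.0 - scheme.p_match)
    g = 0
    for v in values:
        g = math.gcd(g, abs(v))
    g = max(g, 1)
    rescaled = {v // g: p for v, p in values.items()}
    low = min(rescaled)
    probs = np.zeros(max(rescaled) - low + 1)
    for v, p in rescaled.items():
        probs[v - low] += p
    return probs, low, g


def estimate_K(scheme: ScoringScheme, lam: float, tol: float = 1e-6, max_terms: int = 10000) -> float:
    """K by the lattice series method; see the module docstring.

    The series is truncated when successive partial K estimates differ
    by less than ``tol``; exceeding ``max_terms`` convolution steps
    raises :class:`KConvergenceError`. The result must lie in (0, 1).
    """
    step, low, g = _step_distribution(scheme)
    lam_r = lam * g  # lambda in rescaled (gcd) score units
    # relative entropy H = lambda * E[X exp(lambda X)] (rescale-invariant)
    svals = low + np.arange(len(step))
    H = lam_r * float(np.sum(step * svals * np.exp(lam_r * svals)))
    if H <= 0:  # pragma: no cover - guarded by estimate_lambda preconditions
        raise KConvergenceError("non-positive relative entropy")
    prefactor = lam_r / (H * (1.0 - math.exp(-lam_r)))

    sigma = 0.0
    dist = None
    lowk = 0
    prev_K = None
    for k in range(1, max_terms + 1):
        dist = step if dist is None else np.convolve(dist, step)
        lowk += low
        scores_k = lowk + np.arange(len(dist))
        neg = scores_k < 0
        term = float(dist[~neg].sum() + np.sum(dist[neg] * np.exp(lam_r * scores_k[neg])))
        sigma += term / k
        K = prefactor * math.exp(-2.0 * sigma)
        if prev_K is not None and abs(K - prev_K) < tol:
            if not 0.0 < K < 1.0:
                raise KConvergenceError(f"K={K:.4g} outside (0, 1)")
            return K
        prev_K = K
    raise KConvergenceError(f"K series did not converge within {max_terms} terms")


def karlin_evalue(params: KarlinParams, m: int, n: int, S: float) -> float:
    """Expected number of chance MSPs scoring >= S: ``K*m*n*exp(-lambda*S)``.

    ``m`` is the MSP sequence length and ``n`` the database size
    (1 when no database is searched).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return params.K * m * n * math.exp(-params.lambda_ * S)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _msp_scan(a_arr: np.ndarray, b_arr: np.ndarray, match: int, mismatch: int, chunk: int = 512):
    """All top-scoring ungapped segments over the diagonals of a x b.

    Returns ``(score, candidates)`` where each candidate is
    ``(a_start, b_start, length)`` in the frame of the given arrays.
    Per-diagonal maxima come from the prefix-sum form of the
    maximum-subarray scan, vectorised across diagonals in chunks; all
    positions achieving the global maximum are enumerated so the
    caller can apply its tie-break in reported coordinates.
    """
    la, lb = len(a_arr), len(b_arr)
    dlen = min(la, lb)
    all_offsets = np.arange(-(lb - 1), la)
    t_idx = np.arange(dlen)
    top = None
    candidates: list[tuple[int, int, int]] = []
    for c0 in range(0, len(all_offsets), chunk):
        offsets = all_offsets[c0 : c0 + chunk]
        I = t_idx[None, :] + np.maximum(offsets, 0)[:, None]
        J = t_idx[None, :] + np.maximum(-offsets, 0)[:, None]
        valid = (I < la) & (J < lb)
        X = np.where(
            a_arr[np.minimum(I, la - 1)] == b_arr[np.minimum(J, lb - 1)], match, mismatch
        ).astype(np.int64)
        X[~valid] = _NEG
        C = np.cumsum(X, axis=1)
        zero = np.zeros((C.shape[0], 1), dtype=np.int64)
        prefix = np.concatenate([zero, C[:, :-1]], axis=1)
        runmin = np.minimum.accumulate(prefix, axis=1)
        gains = C - runmin
        diag_best = gains.max(axis=1)
        chunk_top = int(diag_best.max())
        if top is None or chunk_top > top:
            top = chunk_top
            candidates = []
        if chunk_top < top:
            continue
        for row in np.flatnonzero(diag_best == top):
            off = int(offsets[row])
            cum = np.concatenate([[0], C[row]])
            for t_end in np.flatnonzero(gains[row] == top):
                t_end = int(t_end)
                target = int(C[row, t_end]) - top
                # every prefix index with C == target starts a maximal segment
                for t_start in np.flatnonzero(cum[: t_end + 1] == target):
                    t_start = int(t_start)
                    length = t_end - t_start + 1
                    candidates.append(
                        (t_start + max(off, 0), t_start + max(-off, 0), length)
                    )
    return top, candidates


def find_msp(a: str, b: str, scheme: ScoringScheme | None = None) -> MSP:
    """Maximum-score ungapped segment pair over all diagonals of both
    orientations; ties broken by smaller a_start, then smaller b_start
    (reported on b's forward coordinates), then forward orientation."""
    if scheme is None:
        scheme = ScoringScheme()
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    a_arr = _encode(a.upper())
    b_fwd = b.upper()
    lb = len(b_fwd)

    best = None  # (score, -a_start, -b_start, forward?, length)
    score_f, cands_f = _msp_scan(a_arr, _encode(b_fwd), scheme.match, scheme.mismatch)
    for a0, b0, length in cands_f:
        cand = (score_f, -a0, -b0, True, length)
        if best is None or cand[:4] > best[:4]:
            best = cand
    b_rc = reverse_complement(b_fwd)
    score_r, cands_r = _msp_scan(a_arr, _encode(b_rc), scheme.match, scheme.mismatch)
    for a0, b0_rc, length in cands_r:
        cand = (score_r, -a0, -(lb - b0_rc - length), False, length)
        if best is None or cand[:4] > best[:4]:
            best = cand
    score, neg_a, neg_b, forward, length = best
    return MSP(
        score=score,
        length=length,
        a_start=-neg_a,
        b_start=-neg_b,
        orientation="+" if forward else "-",
    )


def dot_matrix(
    a: str,
    b: str,
    window: int = 25,
    cutoff: int | None = None,
    scheme: ScoringScheme | None = None,
) -> DotPlot:
    """Dot-plot comparison of two sequences.

    A hit is emitted at every window-pair start ``(i, j)`` — on the
    forward strand and against b's reverse complement — whose ungapped
    windowed score reaches ``cutoff`` (default ``20 * match``, a
    20-identities-equivalent stringency).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if cutoff is None:
        cutoff = 20 * scheme.match
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    a = a.upper()
    b = b.upper()
    if window > len(a) or window > len(b):
        raise ValueError("window longer than one of the sequences")

    a_arr = _encode(a)
    hits: list[tuple[int, int, str]] = []
    for strand, b_seq in (("+", b), ("-", reverse_complement(b))):
        b_arr = _encode(b_seq)
        per_pos = np.where(a_arr[:, None] == b_arr[None, :], scheme.match, scheme.mismatch).astype(
            np.int32
        )
        n_i = len(a) - window + 1
        n_j = len(b) - window + 1
        W = np.zeros((n_i, n_j), dtype=np.int32)
        for t in range(window):
            W += per_pos[t : t + n_i, t : t + n_j]
        for i, j in np.argwhere(W >= cutoff):
            j_fwd = int(j) if strand == "+" else len(b) - int(j) - window
            hits.append((int(i), j_fwd, strand))
    return DotPlot(window=window, cutoff=int(cutoff), hits=hits, n_dots=len(hits))
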