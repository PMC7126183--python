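# Methods

## Simulation model

A template is a single DNA string of length G over {A,C,G,T} (N is
accepted on input but never generated). Shotgun sequencing in the
Sanger regime is modelled as draws of fixed-length, error-free reads:

* **Stopping rule.** Reads are emitted until total sequenced bases /
  G reaches the coverage c, i.e. exactly `N = ceil(c·G/L)` reads. The
  read count is therefore deterministic given (G, L, c); only
  positions and strands are random. A run always satisfies
  `c·G ≤ N·L < c·G + L`.
* **Placement.** Linear mode draws starts uniformly on `[0, G−L]`
  (the whole read fits on the string); circular mode draws on
  `[0, G)` and wraps through the origin. Linear mode under-covers the
  template ends (base 0 is covered only by reads starting exactly at
  0), which is what produces assemblies shorter than the reference
  and, together with reverse-orientation merges, the "impaired
  topology" artifact; circular mode is depth-uniform.
* **Strand.** Each read is independently reverse-complemented with
  probability `reverse_fraction` (default 0.5 — both strands are
  sequenced in practice).
* **Reads are error-free and of exactly length L.** Sanger chemistry
  is accurate enough that a substitution model would not change the
  contig-count statistics this package studies; length variation is
  likewise out of scope. The assembler's identity threshold (< 1)
  nevertheless leaves room for future error models.
* **Reproducibility contract.** One `numpy.random.default_rng(seed)`
  stream, consumed in a fixed order: per read, start first
  (`rng.integers`), then strand (`rng.random() < reverse_fraction`).
  Read ids are `r{i}` in generation order.

The fixture generator draws bases i.i.d. with P(G)=P(C)=gc/2,
P(A)=P(T)=(1−gc)/2. Real cloning vectors sit around 40–60% GC; the
synthetic defaults used in tests (uniform or mid-50s GC at lengths
2319/4079/4886) emulate that regime. What synthetic templates do NOT
have is the repeat structure of real vectors (long terminal repeats,
multiple cloning sites shared between vectors), so repeat-induced
misassembly rates measured here are lower bounds on real data.

## Greedy assembly

TIGR-style greedy overlap-layout-consensus:

1. Score all pairwise suffix–prefix *ungapped* overlaps, in both
   orientations when `consider_reverse` is set. An overlap of length
   k passes if `k ≥ min_overlap` (T, default 40 nt) and its mismatch
   fraction is ≤ 1 − `min_identity` (default 0.95).
2. Merge the pair with the longest passing overlap. Ties: fewer
   mismatches, then lexicographically smallest ordered id pair, then
   forward before reverse orientation — fully deterministic.
3. Recompute overlaps involving the merged contig; repeat until no
   pair passes. Unmerged reads remain as singleton contigs, so
   `unplaced` is empty by construction.

Merges are pairwise, so a merged column holds two bases and the
"majority with ties toward the earlier-merged base" consensus reduces
to keeping the leading sequence verbatim: `merged = a + b[k:]`.
Error-free reads make the point moot (overlaps have zero mismatches).

**Seed-and-extend candidate filter.** Any passing overlap of length k
with `m = floor(k(1−identity))` mismatches contains an exact run of
`≥ ceil((k−m)/(m+1))` bases (pigeonhole), 13 nt at the default
thresholds. Candidate pairs are therefore restricted to sequences
sharing an exact seed k-mer of that guaranteed length (capped at 32;
shorter is always safe). The filter is lossless and makes the
all-pairs stage near-linear for error-free reads. Overlap search per
candidate scans shifts longest-first and stops at the first passing
length.

**Thresholds.** T = 40 nt and identity 0.95 are classic shotgun
practice; both are exposed in `AssemblyParams`. Lowering T below ~15
erodes the specificity of overlap detection on 4-letter DNA
(random 15-mers collide at rate 4⁻¹⁵); raising it above L/2 makes
short-read assembly impossible.

**Island oracle.** With true read coordinates, reads whose template
intervals overlap by ≥ T form connected components ("islands") — the
theory-level contig count. Because all simulated reads share one
length, connectivity is consecutive-only after sorting by start, and
the circular case just adds the wraparound gap. The greedy assembler
agrees with the oracle on ≥ 95% of error-free simulations; the
residual disagreements are repeat-induced joins of intervals the
oracle keeps apart (chance k-mer repeats in random templates).

## Lander–Waterman cross-check

Expected island count `N·exp(−c(1−θ))`, θ = T/L, c = NL/G. The
closed form assumes edge-free placement; it matches circular-mode
simulations within Monte-Carlo error, while linear mode carries an
O(L/G) edge deficit (the exact fixed-N circular expectation is
`N·(1−(L−T)/G)^(N−1)`). Tests therefore compare against circular-mode
simulations.

## Karlin–Altschul statistics

For match score +a, mismatch −b (defaults +5/−4) and background
composition p (estimated from the inputs, uniform fallback), with
negative expected score and a positive achievable score:

* λ is the unique positive root of
  `Σᵢⱼ pᵢpⱼ exp(λ s(i,j)) = 1`, found by Brent bracketing to
  `xtol = 1e−12` (residual ≤ 1e−9).
* K uses the classical lattice series. Scores are rescaled by their
  gcd g (segment scores of varying length populate g·Z), and with
  relative entropy `H = λ·E[X e^{λX}]` and
  `σ = Σ_{k≥1} (1/k)·(P(S_k ≥ 0) + E[e^{λS_k}; S_k < 0])`
  (S_k the k-step score walk, computed by iterated convolution),
  `K = λg·e^{−2σ} / (H·(1 − e^{−λg}))`. Terms decay geometrically, and
  the series stops when successive K estimates differ by < 1e−6
  (cap 10⁴ terms). The implementation reproduces the exact
  gambler's-ruin value K = (q−p)²/q = 1/3 for ±1 scoring at uniform
  composition and the classical ≈ 0.175 for +5/−4, and is validated
  in tests against a Monte-Carlo excursion-counting oracle.
* E-value: `E = K·m·n·e^{−λS}` with m the MSP length and n the
  database size (default 1: no database). Note that for a same-length
  self-comparison class of inputs with K≈0.17, λ≈0.19, m≈213, S≈39
  this evaluates to ≈ 2.2×10⁻², not 2×10⁻³; the formula is
  implemented exactly as written.

**MSP.** Per-diagonal maximum-subarray scan in prefix-sum form
(`max_t (C_t − min_{s<t} C_s)`), vectorised across diagonals in
chunks, over both orientations. All positions achieving the global
maximum are enumerated and the tie-break (smaller a_start, then
smaller b_start on b's forward coordinates, then forward orientation)
is applied to the reported coordinates. Verified against an
exhaustive all-segment-pairs oracle on short sequences.

**Dot plot.** Every window pair (default 25 nt) on the forward strand
and against the reverse complement scores its ungapped window; hits
are window starts with score ≥ cutoff (default 20·match, a
20-identities-equivalent stringency). Reverse-strand hits are
reported on b's forward coordinates, so reverse similarity appears as
negative-slope diagonals. Hit counts depend strongly on the
window/cutoff convention, so they are reported, never asserted.

## Sequence metrics

* **Composition.** GC% and AT% over A+C+G+T (N excluded from
  numerator and denominator). ssDNA molecular weight sums per-residue
  masses (A 313.21, C 289.18, G 329.21, T 304.20 Da) plus a 79.0 Da
  terminal adjustment; the constants are arguments because published
  tools differ in their conventions, so absolute MW values should not
  be compared across programs.
* **Identity.** Global (end-to-end) pairwise alignment via
  Biopython's `PairwiseAligner` (match +1, mismatch −1, linear gap
  −2), identity = matches / all alignment columns including gapped
  ones — missing sequence is penalised, which is what makes the
  linear-simulation edge losses visible. Tie-break among co-optimal
  alignments is the aligner's canonical first alignment; the identity
  value itself is tie-invariant.
* **Copy number.** `n = a·N_A/(l·650·10⁹)` exactly as printed, with a
  in ng, l in nt and 650 Da per base pair.
* **Topology.** `exact` / `rotation` (substring of the doubled
  reference at equal length) are string checks. Otherwise the shared
  region is anchored on the forward-orientation MSP diagonal; the
  reference prefix and assembled suffix falling outside it are
  compared after reverse-complementing the suffix, and `impaired` is
  declared when both spans are ≥ `min_block` (50 nt) with ≥ 90%
  global identity. Anything else is `mismatch`.

## Sweep and fits

Grid cells get the seed
`base_seed·10⁶ + template_idx·10⁴ + L_idx·10³ + c_idx·10 + replicate`,
so any cell reruns independently; this caps replicates at 10.
Linear fits use OLS with r² = squared Pearson correlation and the
slope F-test `F = (n−2)r²/(1−r²)` on (1, n−2) dof. Gaussian fits use
`scipy.optimize.least_squares` with A₀ = max y, μ₀ = x at the maximum
of y, σ₀ = range(x)/4, ftol 1e−10, ≤ 10⁴ evaluations; σ is reported
positive, r² = 1 − SS_res/SS_tot (unclamped, so poor fits can go
negative), and asymptotic standard errors come from the Jacobian at
the optimum. Gaussian summaries are fitted to replicate *means* per
coverage; per-replicate points remain available in the sweep table.

Problem sizes used by the test suite and the acceptance script —
three templates (4079/4886/2319 nt), read lengths 100/400/800,
coverages 1–9, 3–5 replicates — mirror a realistic desk-scale plasmid
study; contig statistics at L = 100 use 5 replicates because the
Gaussian r² stabilises there.

## Known limitations

* No base-calling errors, quality values, chromatograms, or read
  length variation; no gapped overlap detection.
* The greedy assembler implements none of TIGR Assembler's clone
  constraints or repeat resolution; on repeat-rich templates it will
  misjoin.
* Dot-plot hit counts and absolute MW values are
  convention-dependent (documented above) and only reported.
* The copy-number formula is exposed for experiment planning; PCR
  amplification itself (cycle efficiency, primer design) is out of
  scope.
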