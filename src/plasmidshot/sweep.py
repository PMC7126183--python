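"""Coverage x read-length sweep experiments and curve fits.

The sweep reruns the simulate-then-assemble pipeline over a grid of
(template, read length L, coverage c, replicate) cells and tabulates
read and contig counts. Two summary models are fitted:

* read count vs coverage is linear (the stopping rule makes
  ``n_reads = ceil(c*G/L)``), summarised by ordinary least squares
  with the slope's F-test p-value;
* contig count vs coverage at short read lengths rises and falls,
  summarised by a Gaussian curve ``y = A*exp(-(x-mu)^2/(2*sigma^2))``
  fitted by nonlinear least squares.

``lander_waterman_expected_contigs`` provides the classical
closed-form island expectation ``N*exp(-c*(1-theta))`` (theta = T/L)
as an analytic cross-check for the simulated contig counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from plasmidshot.seqio import SequenceRecord, random_plasmid
from plasmidshot.simulator import SimulationParams, required_read_count, simulate_reads
from plasmidshot.assembler import AssemblyParams, greedy_assemble


@dataclass
class SweepConfig:
    """The experiment grid.

    templates
        :class:`SequenceRecord` templates, or ``(length, gc, seed)``
        tuples expanded through :func:`~plasmidshot.seqio.random_plasmid`.
    read_lengths / coverages
        Grid axes; defaults are the 100/400/800 nt read lengths and
        coverages 1..9 of a plasmid-scale sweep.
    replicates
        Independent repetitions per cell (default 3; at most 10 so the
        per-cell seed derivation below stays collision-free).
    assembler
        Greedy-assembler thresholds applied to every cell.
    base_seed
        Root seed. Each cell uses
        ``base_seed*10**6 + t_idx*10**4 + L_idx*10**3 + c_idx*10 + replicate``
        so any single cell is independently reproducible.
    """

    templates: list
    read_lengths: list[int] = field(default_factory=lambda: [100, 400, 800])
    coverages: list[float] = field(default_factory=lambda: [float(c) for c in range(1, 10)])
    replicates: int = 3
    assembler: AssemblyParams = field(default_factory=AssemblyParams)
    reverse_fraction: float = 0.5
    circular: bool = False
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("templates must be non-empty")
        if not self.read_lengths:
            raise ValueError("read_lengths must be non-empty")
        if not self.coverages:
            raise ValueError("coverages must be non-empty")
        if not 1 <= self.replicates <= 10:
            raise ValueError(f"replicates must be in 1..10, got {self.replicates}")

    def resolved_templates(self) -> list[SequenceRecord]:
        out = []
        for t in self.templates:
            if isinstance(t, SequenceRecord):
                out.append(t)
            else:
                length, gc, seed = t
                out.append(random_plasmid(length, gc, seed, circular=self.circular))
        return out


@dataclass
class SweepRecord:
    """One grid cell: counts from a single simulate+assemble run.

    ``n_contigs`` is None when the sweep was run with ``assemble=False``
    (read counting only).
    """

    template_id: str
    template_length: int
    read_length: int
    coverage: float
    replicate: int
    n_reads: int
    n_contigs: int | None
    seed_used: int


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


@dataclass
class GaussianFit:
    amplitude: float
    mean: float
    sd: float
    r_squared: float
    converged: bool
    # asymptotic standard errors of (amplitude, mean, sd) from the
    # Jacobian at the optimum; None when the information matrix is
    # singular or the fit leaves no residual degrees of freedom
    stderr: tuple[float, float, float] | None = None


def cell_seed(base_seed: int, template_index: int, L_index: int, c_index: int, replicate: int) -> int:
    """Deterministic per-cell seed (see :class:`SweepConfig`)."""
    return base_seed * 10**6 + template_index * 10**4 + L_index * 10**3 + c_index * 10 + replicate


def run_sweep(config: SweepConfig, assemble: bool = True) -> list[SweepRecord]:
    """Run every (template, read length, coverage, replicate) cell.

    Validates the whole grid (every read length against every template)
    before simulating anything.
    """
    templates = config.resolved_templates()
    for template in templates:
        for L in config.read_lengths:
            if L > len(template.sequence):
                raise ValueError(
                    f"read length {L} exceeds template {template.id!r} "
                    f"length {len(template.sequence)}"
                )
    records: list[SweepRecord] = []
    for ti, template in enumerate(templates):
        for li, L in enumerate(config.read_lengths):
            for ci, c in enumerate(config.coverages):
                for rep in range(config.replicates):
                    seed = cell_seed(config.base_seed, ti, li, ci, rep)
                    params = SimulationParams(
                        read_length=L,
                        coverage=c,
                        reverse_fraction=config.reverse_fraction,
                        circular=config.circular,
                        seed=seed,
                    )
                    readset = simulate_reads(template, params)
                    n_contigs: int | None = None
                    if assemble:
                        n_contigs = (
                            greedy_assemble(readset, config.assembler).n_contigs
                            if readset.reads
                            else 0
                        )
                    records.append(
                        SweepRecord(
                            template_id=template.id,
                            template_length=len(template.sequence),
                            read_length=L,
                            coverage=c,
                            replicate=rep,
                            n_reads=len(readset.reads),
                            n_contigs=n_contigs,
                            seed_used=seed,
                        )
                    )
    return records


def sweep_dataframe(records: list[SweepRecord]) -> pd.DataFrame:
    """Sweep records as a tidy DataFrame (one row per cell)."""
    return pd.DataFrame([vars(r) for r in records])


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on x.

    r^2 is the squared Pearson correlation; the p-value is the slope's
    F-test with (1, n-2) degrees of freedom (identical to the slope
    t-test for simple regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: degenerate design")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = x.size
    if 1.0 - r2 <= 0:
        p = 0.0
    else:
        F = (n - 2) * r2 / (1.0 - r2)
        p = float(stats.f.sf(F, 1, n - 2))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        p_value=p,
        n_points=int(n),
    )


def _gaussian(params, x):
    A, mu, sd = params
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def fit_gaussian(x, y) -> GaussianFit:
    """Nonlinear least squares of ``y = A*exp(-(x-mu)^2/(2*sigma^2))``.

    Initialisation: A0 = max(y), mu0 = x at the maximum of y,
    sigma0 = (max(x)-min(x))/4. Convergence when the relative change
    in the residual sum of squares falls below 1e-10, capped at 1e4
    function evaluations; sigma is returned positive by convention.
    r^2 = 1 - SS_res/SS_tot (can be negative for poor fits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired points")
    if not np.any(y > 0):
        raise ValueError("all-zero (or non-positive) y: degenerate data")
    x0 = np.array([float(y.max()), float(x[int(np.argmax(y))]), max(np.ptp(x) / 4.0, 1e-6)])
    res = least_squares(
        lambda p: _gaussian(p, x) - y,
        x0,
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=10**4,
    )
    A, mu, sd = res.x
    yhat = _gaussian(res.x, x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("-inf"))
    stderr = None
    dof = x.size - 3
    if dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (ss_res / dof)
            stderr = tuple(float(v) for v in np.sqrt(np.maximum(np.diag(cov), 0.0)))
        except np.linalg.LinAlgError:
            stderr = None
    return GaussianFit(
        amplitude=float(A),
        mean=float(mu),
        sd=float(abs(sd)),
        r_squared=r2,
        converged=bool(res.success),
        stderr=stderr,
    )


def lander_waterman_expected_contigs(
    template_length: int, read_length: int, n_reads: int, min_overlap: int
) -> float:
    """Classical expected island count ``N*exp(-c*(1-theta))`` with
    ``c = N*L/G`` and ``theta = T/L``.

    The closed form assumes edge-free (circular or effectively
    infinite) placement of read starts; linear-mode simulations carry
    an O(L/G) edge deficit relative to it.
    """
    if template_length < 1 or read_length < 1:
        raise ValueError("lengths must be >= 1")
    if n_reads < 0:
        raise ValueError(f"n_reads must be >= 0, got {n_reads}")
    if not 0 <= min_overlap < read_length:
        raise ValueError("min_overlap must satisfy 0 <= T < L")
    if n_reads == 0:
        return 0.0
    c = n_reads * read_length / template_length
    theta = min_overlap / read_length
    return n_reads * math.exp(-c * (1.0 - theta))
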