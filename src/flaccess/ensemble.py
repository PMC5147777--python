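"""Monte-Carlo ensembles over House-of-Cards landscapes.

Accessibility ``A`` is the probability that a randomly drawn landscape
contains at least one admissible fitness-increasing path from the
antipodal genotype to the global maximum.  This module estimates ``A``
and related ensemble statistics (path counts, step-class fractions,
coverage) over independent landscape replicates, extrapolates the
large-``N`` limit ``A_inf`` from curves of ``A`` against ``1/log2(N)``,
and locates the critical initial fitness ``f_crit`` at which ``A(f0)``
collapses.

Every experiment takes one seed; replicate sub-streams are spawned
deterministically from it, so identical (seed, configuration) pairs give
bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels
from .landscape import FitnessLandscape, LandscapeShape, generate_hoc
from .paths import MODES, PathQuery, coverage, _MODE_CODES

__all__ = [
    "EnsembleEstimate",
    "AsymptoticFit",
    "CriticalFitness",
    "PathCountCurve",
    "ClassFractionSummary",
    "CoverageSummary",
    "estimate_accessibility",
    "accessibility_curve",
    "extrapolate_A_inf",
    "accessibility_vs_f0",
    "path_count_vs_f0",
    "class_fraction_summary",
    "coverage_summary",
]

#: Exact-counting experiments refuse landscapes above this size by default.
MAX_COUNTING_N = 2**20
#: Accessibility / coverage experiments refuse above this size by default.
MAX_ACCESS_N = 2**24


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _check_bound(shape: LandscapeShape, bound: int, what: str) -> None:
    if shape.N > bound:
        raise ValueError(
            f"{what} refuses N={shape.N} > {bound} genotypes "
            f"({shape.N * 8 / 1e9:.1f} GB of fitness values per replicate); "
            "raise the bound explicitly if you have the resources"
        )


def _hoc_fitness(shape: LandscapeShape, child: np.random.SeedSequence, f0: float | None):
    """Fitness vector of one replicate, optionally f0-conditioned.

    Returns ``(fitness, feasible)``; ``feasible`` is False when ``f0``
    meets or exceeds the target fitness, in which case no strictly
    increasing path can exist and the replicate counts as inaccessible.
    """
    fitness = generate_hoc(shape, child).fitness
    if f0 is None:
        return fitness, True
    if f0 >= fitness[shape.N - 1]:
        return fitness, False
    fitness[0] = f0
    return fitness, True


@dataclass
class EnsembleEstimate:
    """Accessibility (and optional companions) of one landscape ensemble."""

    shape: LandscapeShape
    mode: str
    n_replicates: int
    n_accessible: int
    f0: float | None = None
    mean_n_paths: float | None = None
    median_n_paths: float | None = None
    class_fractions: dict | None = None
    mean_path_length: float | None = None
    mean_coverage_accessible: float | None = None
    mean_coverage_all: float | None = None

    @property
    def accessibility(self) -> float:
        return self.n_accessible / self.n_replicates

    @property
    def std_error(self) -> float:
        a = self.accessibility
        return math.sqrt(a * (1.0 - a) / self.n_replicates)


def estimate_accessibility(
    shape: LandscapeShape,
    mode: str = "all",
    n_replicates: int = 1000,
    seed=0,
    f0: float | None = None,
    max_n: int = MAX_ACCESS_N,
) -> EnsembleEstimate:
    """Monte-Carlo estimate of accessibility ``A`` with binomial errors."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    _check_bound(shape, max_n, "estimate_accessibility")
    code = _MODE_CODES[mode]
    powers = shape.powers
    target = shape.N - 1
    n_acc = 0
    for child in _seedseq(seed).spawn(n_replicates):
        fitness, feasible = _hoc_fitness(shape, child, f0)
        if feasible and _kernels.dfs_accessible(
            fitness, shape.K, shape.L, powers, code, 0, target
        ):
            n_acc += 1
    return EnsembleEstimate(shape, mode, n_replicates, n_acc, f0=f0)


def accessibility_curve(
    K: int,
    mode: str,
    L_values: Sequence[int],
    reps: int | dict | Callable[[int], int],
    seed=0,
    f0: float | None = None,
    max_n: int = MAX_ACCESS_N,
) -> list[EnsembleEstimate]:
    """Accessibility against landscape size ``N = K**L`` along ``L_values``.

    ``reps`` may be a single replicate count, a mapping ``L -> count`` or
    a callable; fewer replicates at the largest sizes keep curves
    affordable while the better-resolved small-``N`` points anchor the
    extrapolation.
    """
    ss = _seedseq(seed)
    children = ss.spawn(len(L_values))
    out = []
    for L, child in zip(L_values, children):
        if callable(reps):
            n = reps(L)
        elif isinstance(reps, dict):
            n = reps[L]
        else:
            n = int(reps)
        out.append(
            estimate_accessibility(
                LandscapeShape(K, L), mode, n, seed=child, f0=f0, max_n=max_n
            )
        )
    return out


@dataclass
class AsymptoticFit:
    """Linear fit of ``A`` against ``1/log2(N)``; ``A_inf`` is the intercept."""

    K: int
    mode: str
    slope: float
    intercept: float
    min_N: int
    n_points: int

    @property
    def A_inf(self) -> float:
        return min(1.0, max(0.0, self.intercept))


def extrapolate_A_inf(
    curve: Iterable[EnsembleEstimate], min_N: int = 2**10
) -> AsymptoticFit:
    """Extrapolate the infinite-size accessibility from a curve.

    Least-squares line of ``A`` on ``1/log2(N)`` over the points with
    ``N > min_N``, weighted by the inverse binomial variance of each
    point (replicate counts usually shrink with ``N``, so the cheap,
    well-resolved small-``N`` points would otherwise be under-used);
    the intercept, clamped to ``[0, 1]``, estimates
    ``A_inf = A(N -> infinity)``.
    """
    pts = [e for e in curve if e.shape.N > min_N]
    if len(pts) < 2:
        raise ValueError(f"need >= 2 curve points with N > {min_N}, got {len(pts)}")
    x = np.array([1.0 / math.log2(e.shape.N) for e in pts])
    y = np.array([e.accessibility for e in pts])
    se = np.array([max(e.std_error, 0.5 / e.n_replicates) for e in pts])
    slope, intercept = np.polyfit(x, y, 1, w=1.0 / se)
    return AsymptoticFit(
        K=pts[0].shape.K,
        mode=pts[0].mode,
        slope=float(slope),
        intercept=float(intercept),
        min_N=min_N,
        n_points=len(pts),
    )


@dataclass
class CriticalFitness:
    """``A(f0)`` on a grid and the interpolated 0.5-crossing ``f_crit``."""

    shape: LandscapeShape
    mode: str
    f0_grid: np.ndarray
    estimates: list[EnsembleEstimate]
    threshold: float = 0.5

    @property
    def A_values(self) -> np.ndarray:
        return np.array([e.accessibility for e in self.estimates])

    @property
    def f_crit(self) -> float | None:
        """Abscissa where linearly interpolated ``A(f0)`` crosses the
        threshold; ``None`` when the grid never brackets a crossing."""
        a = self.A_values
        t = self.threshold
        for i in range(len(a) - 1):
            if a[i] >= t > a[i + 1]:
                x0, x1 = self.f0_grid[i], self.f0_grid[i + 1]
                if a[i] == a[i + 1]:
                    return float(x0)
                return float(x0 + (a[i] - t) / (a[i] - a[i + 1]) * (x1 - x0))
        return None


def accessibility_vs_f0(
    shape: LandscapeShape,
    mode: str = "all",
    f0_grid: Sequence[float] | None = None,
    reps: int = 500,
    seed=0,
    threshold: float = 0.5,
    max_n: int = MAX_ACCESS_N,
) -> CriticalFitness:
    """Accessibility as a function of the initial fitness ``f0``.

    ``A(f0)`` falls steeply near a critical value ``f_crit`` (for large
    ``L`` it approaches ``A_inf``); ``f_crit`` is estimated as the linear
    interpolated crossing of ``A(f0)`` with ``threshold``.
    """
    if f0_grid is None:
        f0_grid = np.linspace(0.0, 0.95, 20)
    f0_grid = np.asarray(f0_grid, dtype=float)
    if np.any(f0_grid < 0) or np.any(f0_grid >= 1):
        raise ValueError("f0 grid values must lie in [0, 1)")
    children = _seedseq(seed).spawn(len(f0_grid))
    estimates = [
        estimate_accessibility(shape, mode, reps, seed=c, f0=float(f0), max_n=max_n)
        for f0, c in zip(f0_grid, children)
    ]
    return CriticalFitness(shape, mode, f0_grid, estimates, threshold)


@dataclass
class PathCountCurve:
    """Mean/median accessible-path counts per ``f0`` grid point."""

    shape: LandscapeShape
    mode: str
    f0_grid: np.ndarray
    mean_counts: np.ndarray  # zeros (inaccessible replicates) included
    median_counts: np.ndarray
    sem_counts: np.ndarray
    n_replicates: int


def path_count_vs_f0(
    shape: LandscapeShape,
    f0_grid: Sequence[float],
    reps: int = 200,
    seed=0,
    mode: str = "all",
    max_n: int = MAX_COUNTING_N,
) -> PathCountCurve:
    """Number of accessible paths against initial fitness.

    Counts are accumulated by the float64 dynamic program (ample
    precision for means over an ensemble); replicates without any
    accessible path contribute zero.
    """
    _check_bound(shape, max_n, "path_count_vs_f0")
    f0_grid = np.asarray(f0_grid, dtype=float)
    code = _MODE_CODES[mode]
    powers = shape.powers
    target = shape.N - 1
    means, medians, sems = [], [], []
    for f0, child in zip(f0_grid, _seedseq(seed).spawn(len(f0_grid))):
        counts = np.empty(reps)
        for i, c in enumerate(child.spawn(reps)):
            fitness, feasible = _hoc_fitness(shape, c, float(f0))
            counts[i] = (
                _kernels.count_paths_float(
                    fitness, shape.K, shape.L, powers, code, 0, target
                )
                if feasible
                else 0.0
            )
        means.append(counts.mean())
        medians.append(np.median(counts))
        sems.append(counts.std(ddof=1) / math.sqrt(reps) if reps > 1 else float("nan"))
    return PathCountCurve(
        shape, mode, f0_grid, np.array(means), np.array(medians), np.array(sems), reps
    )


@dataclass
class ClassFractionSummary:
    """Step-class composition of accessible pathways, two conventions.

    ``landscape_fractions`` (the primary statistic) averages each
    accessible landscape's per-path mean class counts over landscapes
    and divides by the mean path length, so every landscape carries
    equal weight.  ``pooled_fractions`` instead pools raw step counts
    over all paths of all landscapes; landscapes with astronomically
    many pathways dominate that ratio, pushing it toward the
    composition of the path-richest draws.
    """

    shape: LandscapeShape
    mode: str
    n_replicates: int
    n_accessible: int
    landscape_fractions: dict  # forward/backward/distance_neutral -> fraction
    pooled_fractions: dict
    mean_path_length: float  # landscape-averaged per-path mean length
    per_landscape_fractions: np.ndarray | None = None  # (n_acc, 3) f/b/n

    def sem_landscape(self, key: str) -> float:
        """Standard error of the per-landscape fraction for a class."""
        if self.per_landscape_fractions is None or self.n_accessible < 2:
            return float("nan")
        col = {"forward": 0, "backward": 1, "distance_neutral": 2}[key]
        vals = self.per_landscape_fractions[:, col]
        return float(vals.std(ddof=1) / math.sqrt(len(vals)))


def class_fraction_summary(
    shape: LandscapeShape,
    reps: int = 1000,
    seed=0,
    mode: str = "all",
    f0: float | None = None,
    max_n: int = MAX_COUNTING_N,
) -> ClassFractionSummary:
    """Forward/backward/distance-neutral composition of accessible paths.

    Per replicate, the exact-counting dynamic program yields the path
    count and pooled class totals; per-path means (class total / path
    count) are then averaged over accessible landscapes, and the
    fractions are the ratios of those means (equal weight per
    landscape).  The globally pooled ratio is reported alongside.
    """
    _check_bound(shape, max_n, "class_fraction_summary")
    code = _MODE_CODES[mode]
    powers = shape.powers
    target = shape.N - 1
    tot_f = tot_b = tot_m = 0.0
    means = []  # per-landscape per-path mean (forward, backward, neutral)
    for child in _seedseq(seed).spawn(reps):
        fitness, feasible = _hoc_fitness(shape, child, f0)
        if not feasible:
            continue
        n, f, b, m = _kernels.class_totals_float(
            fitness, shape.K, shape.L, powers, code, 0, target
        )
        if n > 0:
            tot_f += f
            tot_b += b
            tot_m += m
            means.append((f / n, b / n, m / n))
    n_acc = len(means)
    nan3 = {"forward": float("nan"), "backward": float("nan"), "distance_neutral": float("nan")}
    if n_acc == 0:
        return ClassFractionSummary(shape, mode, reps, 0, dict(nan3), dict(nan3), float("nan"))
    means = np.array(means)
    mf, mb, mm = means.mean(axis=0)
    mean_len = mf + mb + mm
    landscape = {
        "forward": mf / mean_len,
        "backward": mb / mean_len,
        "distance_neutral": mm / mean_len,
    }
    steps = tot_f + tot_b + tot_m
    pooled = {
        "forward": tot_f / steps,
        "backward": tot_b / steps,
        "distance_neutral": tot_m / steps,
    }
    lengths = means.sum(axis=1, keepdims=True)
    return ClassFractionSummary(
        shape, mode, reps, n_acc, landscape, pooled, float(mean_len),
        per_landscape_fractions=means / lengths,
    )


@dataclass
class CoverageSummary:
    """Mean coverage under both ensemble conventions."""

    shape: LandscapeShape
    mode: str
    n_replicates: int
    n_accessible: int
    mean_accessible_only: float  # over accessible landscapes (NaN if none)
    sd_accessible_only: float
    mean_all: float  # inaccessible landscapes contribute 0
    mean_counts_by_distance: np.ndarray | None = None  # accessible-only


def coverage_summary(
    shape: LandscapeShape,
    reps: int = 50,
    seed=0,
    mode: str = "all",
    f0: float | None = None,
    max_n: int = MAX_ACCESS_N,
) -> CoverageSummary:
    """Mean fraction of genotypes lying on accessible pathways.

    The primary convention averages over accessible landscapes only
    (inaccessible ones have no pathway to cover anything); the
    all-landscape average, where they contribute zero, is also returned.
    """
    _check_bound(shape, max_n, "coverage_summary")
    fractions = []
    dist_counts = None
    n_acc = 0
    for child in _seedseq(seed).spawn(reps):
        fitness, feasible = _hoc_fitness(shape, child, f0)
        if not feasible:
            continue
        res = coverage(FitnessLandscape(shape, fitness), PathQuery(mode))
        if res.accessible:
            n_acc += 1
            fractions.append(res.fraction)
            if dist_counts is None:
                dist_counts = res.counts_by_distance.astype(float)
            else:
                dist_counts = dist_counts + res.counts_by_distance
    if n_acc:
        arr = np.array(fractions)
        mean_acc = float(arr.mean())
        sd_acc = float(arr.std(ddof=1)) if n_acc > 1 else float("nan")
        mean_all = float(arr.sum() / reps)
        dist_counts = dist_counts / n_acc
    else:
        mean_acc = sd_acc = float("nan")
        mean_all = 0.0
    return CoverageSummary(
        shape, mode, reps, n_acc, mean_acc, sd_acc, mean_all, dist_counts
    )
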