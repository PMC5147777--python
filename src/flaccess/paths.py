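"""Exact path analysis on a single fitness landscape.

An *accessible pathway* is a walk on the mutational graph along which
fitness strictly increases at every step.  Because fitness increases
monotonically, the admissible edges form a DAG and every quantity here is
computed by dynamic programming over genotypes sorted by fitness: each
node's contribution is evaluated once and accumulated into its less-fit
predecessors, which reproduces the counter-accumulating backtracking
search exactly while visiting each edge once.

Step classes are defined relative to the target genotype: a step is
*forward* if it decreases the Hamming distance to the target, *backward*
if it increases it, and *distance-neutral* otherwise (only possible for
``K > 2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from . import _kernels
from .landscape import (
    FitnessLandscape,
    LandscapeShape,
    decode,
    distance_to_target,
    hamming_distance,
    set_initial_fitness,
)

__all__ = [
    "PathQuery",
    "PathStats",
    "StepTotals",
    "CoverageResult",
    "MODES",
    "classify_step",
    "admissible_successors",
    "is_accessible",
    "count_paths",
    "step_class_totals",
    "path_stats",
    "coverage",
]

MODES = ("all", "no_backward", "shortest_only")
_MODE_CODES = {"all": 0, "no_backward": 1, "shortest_only": 2}

FORWARD = "forward"
BACKWARD = "backward"
NEUTRAL = "distance_neutral"


@dataclass(frozen=True)
class PathQuery:
    """Which pathway family to analyse.

    ``mode`` selects the admissible step classes: ``"all"`` permits
    forward, backward and distance-neutral steps; ``"no_backward"``
    excludes backward steps; ``"shortest_only"`` keeps forward steps only,
    so every counted path has the minimal length ``L``.  ``f0``, when
    given, overwrites the start genotype's fitness before the analysis
    (conditioning on the initial fitness).
    """

    mode: str = "all"
    start: int = 0
    target: int | None = None  # None means index N - 1
    f0: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def resolve(self, shape: LandscapeShape) -> Tuple[int, int, int]:
        """Return ``(mode_code, start, target)`` for a concrete shape."""
        target = shape.N - 1 if self.target is None else self.target
        if not 0 <= self.start < shape.N or not 0 <= target < shape.N:
            raise IndexError("start/target out of range")
        if self.start == target:
            raise ValueError("start and target genotypes must differ")
        return _MODE_CODES[self.mode], self.start, target


def _prepare(fl: FitnessLandscape, query: PathQuery):
    code, start, target = query.resolve(fl.shape)
    if query.f0 is not None:
        fl = set_initial_fitness(fl, query.f0)
    return fl, code, start, target


def classify_step(a: int, b: int, target: int, shape: LandscapeShape) -> str:
    """Class of the mutational step ``a -> b`` relative to ``target``."""
    if hamming_distance(a, b, shape) != 1:
        raise ValueError(f"genotypes {a} and {b} are not mutational neighbours")
    delta = hamming_distance(b, target, shape) - hamming_distance(a, target, shape)
    if delta == -1:
        return FORWARD
    if delta == 1:
        return BACKWARD
    return NEUTRAL


def admissible_successors(
    g: int, fl: FitnessLandscape, query: PathQuery = PathQuery()
) -> np.ndarray:
    """Strictly fitter neighbours of ``g`` allowed by the query's mode."""
    fl, code, _start, target = _prepare(fl, query)
    shape = fl.shape
    tdig = decode(target, shape)
    fg = fl.fitness[g]
    out = []
    for h in _neighbor_deltas(g, shape, tdig):
        h_idx, delta = h
        if fl.fitness[h_idx] <= fg:
            continue
        if code == 1 and delta > 0:
            continue
        if code == 2 and delta != -1:
            continue
        out.append(h_idx)
    return np.array(sorted(out), dtype=np.int64)


def _neighbor_deltas(g: int, shape: LandscapeShape, target_digits: np.ndarray):
    """Yield ``(neighbor, distance_delta)`` pairs for all neighbours of g."""
    digits = decode(g, shape)
    for p in range(shape.L):
        step = int(shape.powers[p])
        d = int(digits[p])
        t = int(target_digits[p])
        for c in range(shape.K):
            if c == d:
                continue
            delta = (1 if c != t else 0) - (1 if d != t else 0)
            yield g + (c - d) * step, delta


def is_accessible(fl: FitnessLandscape, query: PathQuery = PathQuery()) -> bool:
    """True iff at least one admissible path joins start and target."""
    fl, code, start, target = _prepare(fl, query)
    if target != fl.shape.N - 1:
        # generic target: fall back to the exact Python DP
        return count_paths(fl, PathQuery(query.mode, start, target)) > 0
    return bool(
        _kernels.dfs_accessible(
            fl.fitness, fl.shape.K, fl.shape.L, fl.shape.powers, code, start, target
        )
    )


def _topological_nodes(fitness: np.ndarray) -> np.ndarray:
    """Genotypes ordered by decreasing fitness (successors first)."""
    return np.argsort(fitness, kind="stable")[::-1]


def count_paths(fl: FitnessLandscape, query: PathQuery = PathQuery()) -> int:
    """Exact number of admissible start -> target paths.

    Arbitrary-precision Python integers: counts on empirical-scale
    landscapes reach ~1e21 and computer-generated ones ~1e34, far beyond
    64-bit range.
    """
    fl, code, start, target = _prepare(fl, query)
    shape = fl.shape
    tdig = decode(target, shape)
    fitness = fl.fitness
    counts: list[int] = [0] * shape.N
    counts[target] = 1
    for g in _topological_nodes(fitness):
        g = int(g)
        if g == target:
            continue
        fg = fitness[g]
        total = 0
        for h, delta in _neighbor_deltas(g, shape, tdig):
            if fitness[h] <= fg:
                continue
            if code == 1 and delta > 0:
                continue
            if code == 2 and delta != -1:
                continue
            total += counts[h]
        counts[g] = total
    return counts[start]


@dataclass
class StepTotals:
    """Pooled path count and step-class totals over all admissible paths."""

    n_paths: int | float
    total_forward: int | float
    total_backward: int | float
    total_neutral: int | float

    @property
    def total_steps(self):
        return self.total_forward + self.total_backward + self.total_neutral

    @property
    def mean_length(self) -> float:
        return float(self.total_steps) / float(self.n_paths) if self.n_paths else float("nan")


def step_class_totals(
    fl: FitnessLandscape, query: PathQuery = PathQuery(), exact: bool | None = None
) -> StepTotals:
    """Pooled forward/backward/neutral step totals over all counted paths.

    With ``exact=True`` (default for ``N <= 4096``) the totals are exact
    big integers; otherwise a float64 dynamic program is used, which keeps
    15-16 significant digits — ample for the pooled fractions it feeds.
    """
    fl, code, start, target = _prepare(fl, query)
    shape = fl.shape
    if exact is None:
        exact = shape.N <= 4096
    if not exact and target == shape.N - 1:
        n, f, b, m = _kernels.class_totals_float(
            fl.fitness, shape.K, shape.L, shape.powers, code, start, target
        )
        return StepTotals(n, f, b, m)
    tdig = decode(target, shape)
    fitness = fl.fitness
    n_ = [0] * shape.N
    f_ = [0] * shape.N
    b_ = [0] * shape.N
    m_ = [0] * shape.N
    n_[target] = 1
    for g in _topological_nodes(fitness):
        g = int(g)
        if g == target:
            continue
        fg = fitness[g]
        for h, delta in _neighbor_deltas(g, shape, tdig):
            if fitness[h] <= fg:
                continue
            if code == 1 and delta > 0:
                continue
            if code == 2 and delta != -1:
                continue
            n_[g] += n_[h]
            f_[g] += f_[h] + (n_[h] if delta < 0 else 0)
            b_[g] += b_[h] + (n_[h] if delta > 0 else 0)
            m_[g] += m_[h] + (n_[h] if delta == 0 else 0)
    return StepTotals(n_[start], f_[start], b_[start], m_[start])


class HistogramTooLarge(MemoryError):
    """Raised when the per-node class histograms exceed the configured bound.

    Use :func:`step_class_totals` for pooled totals without the
    length-resolved histogram.
    """


@dataclass
class PathStats:
    """Full exact statistics over all admissible start -> target paths.

    ``class_histogram`` maps ``(n_backward, n_neutral)`` to the number of
    paths with those indirect-step counts; the forward count of each
    bucket is ``d(start, target) + n_backward`` and the path length is
    ``d + 2*n_backward + n_neutral``.
    """

    n_paths: int
    total_forward: int
    total_backward: int
    total_neutral: int
    length_distribution: Dict[int, int] = field(default_factory=dict)
    class_histogram: Dict[Tuple[int, int], int] = field(default_factory=dict)

    @property
    def total_steps(self) -> int:
        return self.total_forward + self.total_backward + self.total_neutral

    @property
    def mean_length(self) -> float:
        return self.total_steps / self.n_paths if self.n_paths else float("nan")

    def to_json(self) -> str:
        """Scalars and the length distribution as JSON.

        Counts are emitted as decimal strings: they routinely exceed the
        exactly-representable integer range of JSON numbers.
        """
        import json

        return json.dumps(
            {
                "n_paths": str(self.n_paths),
                "total_steps": str(self.total_steps),
                "total_forward": str(self.total_forward),
                "total_backward": str(self.total_backward),
                "total_neutral": str(self.total_neutral),
                "length_distribution": {
                    str(k): str(v) for k, v in sorted(self.length_distribution.items())
                },
            },
            indent=2,
        )

    def write_histogram_tsv(self, path) -> None:
        """The 2-D ``(n_backward, n_neutral)`` histogram as TSV.

        Path counts are written as exact integer strings.
        """
        with open(path, "w") as fh:
            fh.write("n_backward\tn_neutral\tpath_count\n")
            for (b, n), c in sorted(self.class_histogram.items()):
                fh.write(f"{b}\t{n}\t{c}\n")


def path_stats(
    fl: FitnessLandscape,
    query: PathQuery = PathQuery(),
    max_cells: int = 2_000_000,
) -> PathStats:
    """Exact path count, step-class totals, length distribution and the
    2-D ``(n_backward, n_neutral)`` histogram.

    Each genotype carries a dictionary histogram of indirect-step counts
    over its paths to the target, accumulated from its fitter neighbours
    in decreasing-fitness order (the generalized-counter scheme).  Raises
    :class:`HistogramTooLarge` when the combined histogram size exceeds
    ``max_cells``.
    """
    fl, code, start, target = _prepare(fl, query)
    shape = fl.shape
    tdig = decode(target, shape)
    fitness = fl.fitness
    hists: list[dict | None] = [None] * shape.N
    hists[target] = {(0, 0): 1}
    cells = 1
    for g in _topological_nodes(fitness):
        g = int(g)
        if g == target:
            continue
        fg = fitness[g]
        hg: dict = {}
        for h, delta in _neighbor_deltas(g, shape, tdig):
            if fitness[h] <= fg:
                continue
            if code == 1 and delta > 0:
                continue
            if code == 2 and delta != -1:
                continue
            hh = hists[h]
            if not hh:
                continue
            db = 1 if delta > 0 else 0
            dn = 1 if delta == 0 else 0
            for (b, m), c in hh.items():
                key = (b + db, m + dn)
                hg[key] = hg.get(key, 0) + c
        hists[g] = hg
        cells += len(hg)
        if cells > max_cells:
            raise HistogramTooLarge(
                f"class histograms exceed {max_cells} cells; "
                "use step_class_totals for pooled totals only"
            )
    hist = hists[start] or {}
    d0 = hamming_distance(start, target, shape)
    n_paths = sum(hist.values())
    total_fwd = sum(c * (d0 + b) for (b, _m), c in hist.items())
    total_bwd = sum(c * b for (b, _m), c in hist.items())
    total_neu = sum(c * m for (_b, m), c in hist.items())
    lengths: Dict[int, int] = {}
    for (b, m), c in hist.items():
        ell = d0 + 2 * b + m
        lengths[ell] = lengths.get(ell, 0) + c
    return PathStats(
        n_paths=n_paths,
        total_forward=total_fwd,
        total_backward=total_bwd,
        total_neutral=total_neu,
        length_distribution=lengths,
        class_histogram=hist,
    )


@dataclass
class CoverageResult:
    """Fraction and distance-resolved counts of genotypes on accessible paths."""

    accessible: bool
    fraction: float
    counts_by_distance: np.ndarray  # length L+1, index = distance to target
    total_by_distance: np.ndarray  # shell sizes C(L,d)(K-1)^d

    @property
    def covered(self) -> int:
        return int(self.counts_by_distance.sum())


def coverage(fl: FitnessLandscape, query: PathQuery = PathQuery()) -> CoverageResult:
    """Genotypes lying on at least one admissible start -> target path.

    A genotype is covered iff it is reachable from the start and
    co-reachable to the target along admissible edges; two single-visit
    reachability sweeps over the DAG suffice, no path enumeration.  An
    inaccessible landscape has coverage 0 by convention.
    """
    from .landscape import genotype_count_by_distance

    fl, code, start, target = _prepare(fl, query)
    shape = fl.shape
    totals = genotype_count_by_distance(shape)
    if target != shape.N - 1:
        raise NotImplementedError("coverage assumes the canonical target N-1")
    fwd = _kernels.reach_forward(fl.fitness, shape.K, shape.L, shape.powers, code, start)
    if not fwd[target]:
        return CoverageResult(False, 0.0, np.zeros(shape.L + 1, dtype=np.int64), totals)
    bwd = _kernels.reach_backward(fl.fitness, shape.K, shape.L, shape.powers, code, target)
    covered = (fwd & bwd).astype(bool)
    covered[start] = True  # start and target always lie on any path
    covered[target] = True
    dist = distance_to_target(shape)
    counts = np.bincount(dist[covered], minlength=shape.L + 1).astype(np.int64)
    return CoverageResult(True, covered.sum() / shape.N, counts, totals)
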