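"""Empirical genotype-fitness tables and sub-landscape ensembles.

Complete (or nearly complete) experimental genotype-fitness tables —
e.g. DNA-protein binding affinities over all 4**10 ten-mers, or
rate constants over all 4**6 RNA recognition sites — are ingested from
TSV, completed (missing genotypes receive the minimum observed fitness)
and normalised to [0, 1].  Two families of sub-landscapes are then
carved out of the full table:

* ``fixed_background`` — fix a random subset of positions to a random
  background; the free positions span a ``K_full**L_sub`` landscape.
* ``binary_pair``      — pick one of the ``C(K,2)`` unordered character
  pairs at every position; the landscape is the induced ``2**L_full``
  hypercube.

Each sub-landscape is re-indexed by per-position character relabelling
(a graph isomorphism) so that its fittest genotype becomes the
all-``K-1`` sequence and a randomly chosen antipodal genotype the
all-zeros sequence, after which the standard accessibility machinery
applies unchanged.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Dict, Iterator, Sequence

import numpy as np

from .landscape import (
    FitnessLandscape,
    LandscapeShape,
    as_rng,
    decode,
    distance_to_target,
    encode,
    shuffle_fitness,
    uniformize_ranks,
)
from .paths import PathQuery, coverage, _MODE_CODES
from . import _kernels

__all__ = [
    "EmpiricalTable",
    "SubLandscapeSpec",
    "ReindexMap",
    "TableFormatError",
    "default_alphabet",
    "sequence_strings",
    "read_table",
    "complete_and_normalize",
    "count_specs",
    "enumerate_or_sample_specs",
    "extract_sublandscape",
    "build_reindex_map",
    "apply_reindex",
    "fitness_distance_profile",
    "sublandscape_ensemble_report",
]


def default_alphabet(K: int) -> str:
    """Conventional character set for alphabet size ``K``."""
    if K == 4:
        return "ACGT"
    if K <= 10:
        return "0123456789"[:K]
    if K <= 26:
        return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:K]
    raise ValueError(f"no default alphabet for K={K}; pass one explicitly")


def sequence_strings(shape: LandscapeShape, alphabet: str) -> list[str]:
    """Sequence string of every genotype index, in index order."""
    if len(alphabet) != shape.K:
        raise ValueError(f"alphabet {alphabet!r} has {len(alphabet)} characters, need {shape.K}")
    out = []
    for g in range(shape.N):
        digits = decode(g, shape)
        out.append("".join(alphabet[d] for d in digits))
    return out


class TableFormatError(ValueError):
    """A genotype-fitness table violates the format contract."""


@dataclass
class EmpiricalTable:
    """A (possibly incomplete) map from sequences to raw fitness values.

    ``alphabet`` is the ordered character set (its order defines the
    digit encoding); sequences are strings of length ``L_full`` over that
    alphabet.  ``records`` may omit genotypes; :func:`complete_and_normalize`
    fills them with the minimum observed fitness.
    """

    alphabet: str
    L_full: int
    records: Dict[str, float]

    @property
    def K_full(self) -> int:
        return len(self.alphabet)

    @property
    def shape(self) -> LandscapeShape:
        return LandscapeShape(self.K_full, self.L_full)

    @property
    def missing_count(self) -> int:
        return self.shape.N - len(self.records)


def read_table(path, alphabet: str) -> EmpiricalTable:
    """Read a ``sequence<TAB>fitness`` TSV into an :class:`EmpiricalTable`.

    An optional single header line is skipped when its second field is
    not numeric.  Ragged sequence lengths, characters outside
    ``alphabet``, duplicate sequences and non-numeric fitness values are
    rejected with the offending line number.  Gzip-compressed files
    (``*.gz``) are read transparently.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    records: Dict[str, float] = {}
    length = None
    charset = set(alphabet)
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableFormatError(
                    f"line {lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            seq, value = parts[0].strip(), parts[1].strip()
            if lineno == 1:
                try:
                    float(value)
                except ValueError:
                    continue  # header line
            try:
                fitness = float(value)
            except ValueError:
                raise TableFormatError(
                    f"line {lineno}: non-numeric fitness value {value!r}"
                ) from None
            if not math.isfinite(fitness):
                raise TableFormatError(f"line {lineno}: non-finite fitness {value!r}")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise TableFormatError(
                    f"line {lineno}: sequence length {len(seq)} differs from {length}"
                )
            bad = set(seq) - charset
            if bad:
                raise TableFormatError(
                    f"line {lineno}: characters {sorted(bad)} outside alphabet {alphabet!r}"
                )
            if seq in records:
                raise TableFormatError(f"line {lineno}: duplicate sequence {seq!r}")
            records[seq] = fitness
    if not records:
        raise TableFormatError("table contains no data rows")
    return EmpiricalTable(alphabet=alphabet, L_full=length, records=records)


def complete_and_normalize(table: EmpiricalTable) -> FitnessLandscape:
    """Fill missing genotypes and rescale fitness onto [0, 1].

    Missing genotypes receive the minimum observed fitness; the affine
    map sends the minimum to 0 and the maximum to 1, leaving observed
    ranks unchanged.  The result covers the full ``K**L`` space but is
    generally *not* canonical (the maximum sits wherever the data put
    it); re-indexing happens per sub-landscape.
    """
    shape = table.shape
    values = np.fromiter(table.records.values(), dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError("degenerate table: all fitness values identical")
    fitness = np.full(shape.N, lo, dtype=np.float64)
    digit = {c: i for i, c in enumerate(table.alphabet)}
    powers = shape.powers
    for seq, f in table.records.items():
        idx = 0
        for p, ch in enumerate(seq):
            idx += digit[ch] * int(powers[p])
        fitness[idx] = f
    fitness = (fitness - lo) / (hi - lo)
    return FitnessLandscape(shape, fitness)


@dataclass(frozen=True)
class SubLandscapeSpec:
    """Constraints carving a sub-landscape out of a full landscape.

    ``fixed_background``: ``positions`` lists the fixed positions and
    ``background`` the character (digit) held at each; the free
    positions form a ``K_full**L_sub`` landscape.

    ``binary_pair``: ``pairs`` gives one unordered digit pair per
    position of the full sequence; the induced landscape is the
    ``2**L_full`` hypercube on those characters (digit 0 = smaller
    character, 1 = larger, before re-indexing).
    """

    variant: str  # "fixed_background" | "binary_pair"
    positions: tuple = ()  # fixed positions, ascending (fixed_background)
    background: tuple = ()  # digits at those positions
    pairs: tuple = ()  # per-position (low, high) digit pairs (binary_pair)

    def __post_init__(self) -> None:
        if self.variant not in ("fixed_background", "binary_pair"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "fixed_background":
            if len(self.positions) != len(self.background):
                raise ValueError("positions and background must have equal length")
            if list(self.positions) != sorted(set(self.positions)):
                raise ValueError("positions must be strictly ascending")
        else:
            for lo, hi in self.pairs:
                if lo >= hi:
                    raise ValueError("binary pairs must be (low, high) with low < high")


def count_specs(
    full_shape: LandscapeShape, variant: str, n_fixed: int | None = None
) -> int:
    """Closed-form number of distinct sub-landscape specs.

    ``fixed_background``: ``C(L, n_fixed) * K**n_fixed`` choices of fixed
    positions and their background characters.  ``binary_pair``:
    ``C(K, 2)**L`` unordered character pairs, one per position.
    """
    K, L = full_shape.K, full_shape.L
    if variant == "fixed_background":
        if n_fixed is None:
            raise ValueError("fixed_background requires n_fixed")
        return math.comb(L, n_fixed) * K**n_fixed
    if variant == "binary_pair":
        return math.comb(K, 2) ** L
    raise ValueError(f"unknown variant {variant!r}")


def _all_specs(full_shape: LandscapeShape, variant: str, n_fixed: int | None) -> Iterator[SubLandscapeSpec]:
    K, L = full_shape.K, full_shape.L
    if variant == "fixed_background":
        for pos in combinations(range(L), n_fixed):
            for bg in product(range(K), repeat=n_fixed):
                yield SubLandscapeSpec("fixed_background", pos, bg)
    else:
        pair_choices = list(combinations(range(K), 2))
        for pairs in product(pair_choices, repeat=L):
            yield SubLandscapeSpec("binary_pair", pairs=tuple(pairs))


def enumerate_or_sample_specs(
    full_shape: LandscapeShape,
    variant: str,
    n_samples: int,
    seed=None,
    n_fixed: int | None = None,
) -> list[SubLandscapeSpec]:
    """Uniform sample of distinct sub-landscape specs, without replacement.

    When ``n_samples`` reaches the total number of distinct specs the
    full enumeration is returned instead (capped, not an error).
    Rejection sampling against a seen-set keeps the draw uniform.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    total = count_specs(full_shape, variant, n_fixed)
    if n_samples >= total:
        return list(_all_specs(full_shape, variant, n_fixed))
    rng = as_rng(seed)
    K, L = full_shape.K, full_shape.L
    seen: set = set()
    out: list[SubLandscapeSpec] = []
    if variant == "fixed_background":
        while len(out) < n_samples:
            pos = tuple(sorted(rng.choice(L, size=n_fixed, replace=False).tolist()))
            bg = tuple(rng.integers(0, K, size=n_fixed).tolist())
            key = (pos, bg)
            if key in seen:
                continue
            seen.add(key)
            out.append(SubLandscapeSpec("fixed_background", pos, bg))
    else:
        pair_choices = list(combinations(range(K), 2))
        while len(out) < n_samples:
            idx = rng.integers(0, len(pair_choices), size=L)
            pairs = tuple(pair_choices[i] for i in idx)
            if pairs in seen:
                continue
            seen.add(pairs)
            out.append(SubLandscapeSpec("binary_pair", pairs=pairs))
    return out


@dataclass(frozen=True)
class ReindexMap:
    """Per-position character permutations implementing a re-indexing.

    ``perms`` is an ``(L, K)`` integer array: ``perms[p, c]`` is the new
    character written wherever character ``c`` occurs at position ``p``.
    Each row is a permutation of ``0..K-1``, so the map is a graph
    isomorphism of the Hamming graph (it preserves every genotype's
    neighbour set).
    """

    shape: LandscapeShape
    perms: np.ndarray

    def __post_init__(self) -> None:
        perms = np.asarray(self.perms, dtype=np.int64)
        if perms.shape != (self.shape.L, self.shape.K):
            raise ValueError("perms must have shape (L, K)")
        for p in range(self.shape.L):
            if sorted(perms[p].tolist()) != list(range(self.shape.K)):
                raise ValueError(f"row {p} of the re-index map is not a permutation")
        object.__setattr__(self, "perms", perms)

    def apply_index(self, g: int) -> int:
        digits = decode(g, self.shape)
        new_digits = self.perms[np.arange(self.shape.L), digits]
        return encode(new_digits, self.shape)


def _complete_permutation(K: int, assigned: dict) -> np.ndarray:
    """Extend partial character assignments to a permutation of 0..K-1.

    Characters that are neither sources nor forced targets stay fixed
    whenever possible; any leftovers are matched in ascending order.
    """
    perm = np.full(K, -1, dtype=np.int64)
    used = set(assigned.values())
    if len(used) != len(assigned):
        raise ValueError("conflicting character assignments")
    for src, dst in assigned.items():
        perm[src] = dst
    free_src = [c for c in range(K) if perm[c] < 0]
    free_dst = [c for c in range(K) if c not in used]
    # keep unassigned characters unchanged where possible
    for c in list(free_src):
        if c in free_dst:
            perm[c] = c
            free_src.remove(c)
            free_dst.remove(c)
    for src, dst in zip(free_src, free_dst):
        perm[src] = dst
    return perm


def build_reindex_map(fl: FitnessLandscape, seed=None) -> ReindexMap:
    """Re-indexing map pinning the fittest genotype to all-``K-1``.

    The fittest genotype (ties broken by lowest index) maps to the
    all-``K-1`` sequence.  For ``K = 2`` the antipodal genotype is then
    forced and the map is the unique per-position bit flip; for
    ``K > 2`` one of the ``(K-1)**L`` antipodal candidates (differing
    from the fittest at every position) is chosen uniformly at random
    and mapped to the all-zeros sequence.  Remaining characters stay
    unchanged where that keeps the row a permutation.
    """
    shape = fl.shape
    rng = as_rng(seed)
    fittest = int(np.argmax(fl.fitness))
    t_digits = decode(fittest, shape)
    perms = np.empty((shape.L, shape.K), dtype=np.int64)
    for p in range(shape.L):
        t = int(t_digits[p])
        others = [c for c in range(shape.K) if c != t]
        a = others[int(rng.integers(0, len(others)))] if shape.K > 2 else others[0]
        assigned = {t: shape.K - 1}
        if a != t:
            assigned[a] = 0
        perms[p] = _complete_permutation(shape.K, assigned)
    return ReindexMap(shape, perms)


def apply_reindex(fl: FitnessLandscape, remap: ReindexMap) -> FitnessLandscape:
    """Relabel genotypes through ``remap``; fitness values move with them."""
    shape = fl.shape
    if remap.shape != shape:
        raise ValueError("re-index map shape does not match the landscape")
    idx = np.arange(shape.N, dtype=np.int64)
    new_idx = np.zeros(shape.N, dtype=np.int64)
    for p in range(shape.L):
        digits = (idx // shape.powers[p]) % shape.K
        new_idx += remap.perms[p][digits] * shape.powers[p]
    out = np.empty(shape.N, dtype=np.float64)
    out[new_idx] = fl.fitness
    return FitnessLandscape(shape, out)


def extract_sublandscape(
    full: FitnessLandscape,
    spec: SubLandscapeSpec,
    seed=None,
    renormalize: bool = True,
) -> FitnessLandscape:
    """Carve out, renormalise and re-index one sub-landscape.

    The selected genotypes' fitness values are gathered into the
    sub-space index order, affinely rescaled onto [0, 1] (rank-preserving,
    hence irrelevant to accessibility) and re-indexed so the fittest
    sub-genotype sits at index ``N_sub - 1``.  ``seed`` drives the
    antipodal choice of the re-indexing for ``K > 2``.
    """
    shape = full.shape
    if spec.variant == "fixed_background":
        fixed = set(spec.positions)
        free = [p for p in range(shape.L) if p not in fixed]
        sub_shape = LandscapeShape(shape.K, len(free))
        base = sum(
            c * int(shape.powers[p]) for p, c in zip(spec.positions, spec.background)
        )
        sub_idx = np.arange(sub_shape.N, dtype=np.int64)
        full_idx = np.full(sub_shape.N, base, dtype=np.int64)
        for q, p in enumerate(free):
            digits = (sub_idx // sub_shape.powers[q]) % shape.K
            full_idx += digits * shape.powers[p]
    elif spec.variant == "binary_pair":
        if len(spec.pairs) != shape.L:
            raise ValueError("binary_pair spec must give one pair per position")
        sub_shape = LandscapeShape(2, shape.L)
        sub_idx = np.arange(sub_shape.N, dtype=np.int64)
        full_idx = np.zeros(sub_shape.N, dtype=np.int64)
        for p, (lo, hi) in enumerate(spec.pairs):
            bit = (sub_idx >> p) & 1
            full_idx += np.where(bit == 1, hi, lo) * shape.powers[p]
    else:  # pragma: no cover - guarded in SubLandscapeSpec
        raise ValueError(spec.variant)
    fitness = full.fitness[full_idx].astype(np.float64)
    if renormalize:
        lo, hi = fitness.min(), fitness.max()
        if hi > lo:
            fitness = (fitness - lo) / (hi - lo)
    sub = FitnessLandscape(sub_shape, fitness)
    remap = build_reindex_map(sub, seed)
    return apply_reindex(sub, remap)


def fitness_distance_profile(fl: FitnessLandscape) -> np.ndarray:
    """Mean fitness per Hamming distance to the target genotype.

    Entry ``d`` averages over the ``C(L, d) * (K-1)**d`` genotypes at
    distance ``d``; entry 0 is the target's own fitness.
    """
    dist = distance_to_target(fl.shape)
    sums = np.bincount(dist, weights=fl.fitness, minlength=fl.shape.L + 1)
    counts = np.bincount(dist, minlength=fl.shape.L + 1)
    return sums / counts


@dataclass
class SubEnsembleCurves:
    """f0-binned accessibility, path-count and coverage curves."""

    bin_centers: np.ndarray
    n_per_bin: np.ndarray
    A_per_bin: np.ndarray  # NaN for empty bins
    mean_paths_per_bin: np.ndarray
    mean_coverage_per_bin: np.ndarray

    @property
    def f_crit(self) -> float | None:
        """Interpolated 0.5-crossing of the binned accessibility curve."""
        mask = self.n_per_bin > 0
        x = self.bin_centers[mask]
        a = self.A_per_bin[mask]
        for i in range(len(a) - 1):
            if a[i] >= 0.5 > a[i + 1]:
                if a[i] == a[i + 1]:
                    return float(x[i])
                return float(x[i] + (a[i] - 0.5) / (a[i] - a[i + 1]) * (x[i + 1] - x[i]))
        return None


@dataclass
class SubEnsembleReport:
    """Accessibility analysis of an empirical sub-landscape ensemble."""

    variant: str
    sub_shape: LandscapeShape
    n_samples: int
    n_accessible: int
    mean_n_paths: float
    median_n_paths: float
    mean_coverage_accessible: float
    mean_profile: np.ndarray  # fitness-to-distance, averaged over samples
    curves: SubEnsembleCurves
    shuffled: "SubEnsembleReport | None" = None

    @property
    def accessibility(self) -> float:
        return self.n_accessible / self.n_samples

    @property
    def std_error(self) -> float:
        a = self.accessibility
        return math.sqrt(a * (1 - a) / self.n_samples)


def _analyse_sublandscapes(
    landscapes: Sequence[FitnessLandscape],
    variant: str,
    mode: str,
    bin_width: float,
) -> SubEnsembleReport:
    code = _MODE_CODES[mode]
    n_bins = int(round(1.0 / bin_width))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    acc_bin = np.zeros(n_bins)
    n_bin = np.zeros(n_bins, dtype=np.int64)
    paths_bin = np.zeros(n_bins)
    cov_bin = np.zeros(n_bins)
    n_acc = 0
    counts = []
    covs = []
    profile = None
    for sub in landscapes:
        uni = uniformize_ranks(sub)
        shape = uni.shape
        prof = fitness_distance_profile(uni)
        profile = prof if profile is None else profile + prof
        f0 = uni.fitness[0]
        b = min(int(f0 / bin_width), n_bins - 1)
        n_paths = _kernels.count_paths_float(
            uni.fitness, shape.K, shape.L, shape.powers, code, 0, shape.N - 1
        )
        accessible = n_paths > 0
        n_bin[b] += 1
        paths_bin[b] += n_paths
        counts.append(n_paths)
        if accessible:
            n_acc += 1
            acc_bin[b] += 1
            cov = coverage(uni, PathQuery(mode)).fraction
            covs.append(cov)
            cov_bin[b] += cov
    with np.errstate(invalid="ignore", divide="ignore"):
        curves = SubEnsembleCurves(
            bin_centers=centers,
            n_per_bin=n_bin,
            A_per_bin=np.where(n_bin > 0, acc_bin / np.maximum(n_bin, 1), np.nan),
            mean_paths_per_bin=np.where(
                n_bin > 0, paths_bin / np.maximum(n_bin, 1), np.nan
            ),
            mean_coverage_per_bin=np.where(
                acc_bin > 0, cov_bin / np.maximum(acc_bin, 1), np.nan
            ),
        )
    counts = np.array(counts)
    return SubEnsembleReport(
        variant=variant,
        sub_shape=landscapes[0].shape,
        n_samples=len(landscapes),
        n_accessible=n_acc,
        mean_n_paths=float(counts.mean()),
        median_n_paths=float(np.median(counts)),
        mean_coverage_accessible=float(np.mean(covs)) if covs else float("nan"),
        mean_profile=profile / len(landscapes),
        curves=curves,
    )


def sublandscape_ensemble_report(
    full: FitnessLandscape,
    variant: str,
    n_samples: int,
    seed=0,
    n_fixed: int | None = None,
    mode: str = "all",
    bin_width: float = 0.05,
    with_shuffled: bool = True,
) -> SubEnsembleReport:
    """Accessibility statistics over sampled sub-landscapes.

    Each sampled sub-landscape is rank-uniformised (so the initial
    fitness is reported on the uniform scale ``f~0``) and analysed
    exactly: accessibility, path count and coverage, pooled overall and
    binned by ``f~0`` on a fixed grid of width ``bin_width``.  When
    ``with_shuffled`` is set, the identical analysis runs on a
    fitness-shuffled counterpart of every sub-landscape, which destroys
    fitness-to-distance correlations while keeping the fitness
    distribution — the randomised baseline of the empirical analysis.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    spec_seed, extract_seed, shuffle_seed = ss.spawn(3)
    specs = enumerate_or_sample_specs(
        full.shape, variant, n_samples, seed=spec_seed, n_fixed=n_fixed
    )
    ex_children = extract_seed.spawn(len(specs))
    subs = [extract_sublandscape(full, sp, seed=c) for sp, c in zip(specs, ex_children)]
    report = _analyse_sublandscapes(subs, variant, mode, bin_width)
    if with_shuffled:
        sh_children = shuffle_seed.spawn(len(subs))
        shuffled = [shuffle_fitness(s, c) for s, c in zip(subs, sh_children)]
        report.shuffled = _analyse_sublandscapes(shuffled, variant, mode, bin_width)
    return report
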