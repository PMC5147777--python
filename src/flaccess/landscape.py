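"""Genotype spaces, Hamming neighbourhoods and fitness-landscape constructors.

A genotype is a sequence of ``L`` characters drawn from a ``K``-letter
alphabet, identified with an integer index in ``[0, K**L)`` by reading the
sequence as a base-``K`` number (position 0 is the least-significant digit).
Two genotypes are mutational neighbours when they differ at exactly one
position, which makes the genotype space a Hamming graph of uniform degree
``(K - 1) * L``.

By convention the globally fittest ("target") genotype sits at index
``N - 1`` (the all-``K-1`` sequence) and adaptive walks start from its
antipodal genotype at index 0 (the all-zeros sequence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LandscapeShape",
    "FitnessLandscape",
    "encode",
    "decode",
    "neighbors",
    "hamming_distance",
    "distance_to_target",
    "genotype_count_by_distance",
    "generate_hoc",
    "set_initial_fitness",
    "shuffle_fitness",
    "uniformize_ranks",
    "write_landscape_tsv",
]


def as_rng(seed: int | np.random.SeedSequence | np.random.Generator | None) -> np.random.Generator:
    """Normalise ``seed`` into a :class:`numpy.random.Generator`."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LandscapeShape:
    """Dimensions of a genotype space: alphabet size ``K`` and length ``L``."""

    K: int
    L: int

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"alphabet size K must be >= 2, got {self.K}")
        if self.L < 1:
            raise ValueError(f"sequence length L must be >= 1, got {self.L}")

    @property
    def N(self) -> int:
        """Total number of genotypes, ``K ** L``."""
        return self.K**self.L

    @property
    def degree(self) -> int:
        """Number of mutational neighbours of every genotype, ``(K-1)*L``."""
        return (self.K - 1) * self.L

    @property
    def powers(self) -> np.ndarray:
        """``K**p`` for positions ``p = 0..L-1`` (int64)."""
        return self.K ** np.arange(self.L, dtype=np.int64)


def encode(digits: Sequence[int] | Iterable[int], shape: LandscapeShape) -> int:
    """Map a length-``L`` digit sequence to its genotype index.

    Position 0 is the least-significant base-``K`` digit.
    """
    digits = np.asarray(list(digits) if not isinstance(digits, np.ndarray) else digits)
    if digits.shape != (shape.L,):
        raise ValueError(f"expected {shape.L} digits, got {digits.shape}")
    if np.any(digits < 0) or np.any(digits >= shape.K):
        raise ValueError(f"digits must lie in [0, {shape.K}), got {digits.tolist()}")
    return int(np.dot(digits.astype(np.int64), shape.powers))


def decode(index: int, shape: LandscapeShape) -> np.ndarray:
    """Inverse of :func:`encode`; returns the length-``L`` digit array."""
    if not 0 <= index < shape.N:
        raise IndexError(f"genotype index {index} out of range [0, {shape.N})")
    return (index // shape.powers) % shape.K


def neighbors(g: int, shape: LandscapeShape) -> np.ndarray:
    """All genotypes at Hamming distance 1 from ``g`` (sorted indices)."""
    if not 0 <= g < shape.N:
        raise IndexError(f"genotype index {g} out of range [0, {shape.N})")
    digits = decode(g, shape)
    out = np.empty(shape.degree, dtype=np.int64)
    i = 0
    for p in range(shape.L):
        step = int(shape.powers[p])
        d = int(digits[p])
        for c in range(shape.K):
            if c != d:
                out[i] = g + (c - d) * step
                i += 1
    out.sort()
    return out


def hamming_distance(a: int, b: int, shape: LandscapeShape) -> int:
    """Number of positions at which genotypes ``a`` and ``b`` differ."""
    return int(np.count_nonzero(decode(a, shape) != decode(b, shape)))


def distance_to_target(shape: LandscapeShape) -> np.ndarray:
    """Hamming distance of every genotype to the target (index ``N-1``).

    Returned as a uint8 vector of length ``N``; the target carries only
    ``K-1`` characters, so the distance is the count of non-``K-1`` digits.
    """
    idx = np.arange(shape.N, dtype=np.int64)
    d = np.zeros(shape.N, dtype=np.uint8)
    for p in range(shape.L):
        d += ((idx // shape.powers[p]) % shape.K != shape.K - 1).astype(np.uint8)
    return d


def genotype_count_by_distance(shape: LandscapeShape) -> np.ndarray:
    """Closed-form shell sizes: ``C(L, d) * (K-1)**d`` for ``d = 0..L``."""
    from math import comb

    return np.array(
        [comb(shape.L, d) * (shape.K - 1) ** d for d in range(shape.L + 1)],
        dtype=np.int64,
    )


@dataclass
class FitnessLandscape:
    """A complete assignment of scalar fitness to every genotype.

    ``fitness`` is a length-``N`` float vector with values in ``[0, 1]``.
    A landscape in *canonical* form carries its maximum at index ``N - 1``
    (the target genotype); constructors in this module always return
    canonical landscapes, while intermediate empirical tables may not yet
    be canonical — use :meth:`validate` to check.
    """

    shape: LandscapeShape
    fitness: np.ndarray

    def __post_init__(self) -> None:
        self.fitness = np.ascontiguousarray(self.fitness, dtype=np.float64)
        if self.fitness.shape != (self.shape.N,):
            raise ValueError(
                f"fitness vector has length {self.fitness.shape}, expected {self.shape.N}"
            )

    def validate(self) -> None:
        """Raise if values leave ``[0, 1]`` or the target is not the maximum."""
        f = self.fitness
        if np.any(f < 0.0) or np.any(f > 1.0):
            raise ValueError("fitness values must lie in [0, 1]")
        if np.argmax(f) != self.shape.N - 1:
            raise ValueError("target genotype (index N-1) must carry the maximum fitness")

    @property
    def is_canonical(self) -> bool:
        return bool(np.argmax(self.fitness) == self.shape.N - 1)

    def copy(self) -> "FitnessLandscape":
        return FitnessLandscape(self.shape, self.fitness.copy())


def _pin_maximum(fitness: np.ndarray) -> np.ndarray:
    """Swap the maximum entry to the last index (target convention), in place."""
    i = int(np.argmax(fitness))
    last = fitness.shape[0] - 1
    if i != last:
        fitness[i], fitness[last] = fitness[last], fitness[i]
    return fitness


def generate_hoc(
    shape: LandscapeShape,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> FitnessLandscape:
    """Draw a House-of-Cards (maximally random) landscape.

    Every genotype receives an i.i.d. uniform-``[0, 1)`` fitness, after
    which the maximum draw is swapped to the target index ``N - 1``.  The
    swap is a relabelling of two exchangeable draws, so marginals are
    untouched; no other re-indexing of the graph is required because the
    Hamming graph is vertex-transitive.
    """
    rng = as_rng(seed)
    fitness = rng.random(shape.N)
    return FitnessLandscape(shape, _pin_maximum(fitness))


def set_initial_fitness(fl: FitnessLandscape, f0: float) -> FitnessLandscape:
    """Condition a landscape on the initial genotype's fitness ``f0``.

    For i.i.d. draws, conditioning on the start fitness is exactly
    equivalent to overwriting ``fitness[0]`` with ``f0``.  ``f0`` must stay
    strictly below the target fitness, otherwise no strictly increasing
    path can exist and the conditioning is ill-posed.
    """
    fmax = float(fl.fitness[fl.shape.N - 1])
    if not 0.0 <= f0 < fmax:
        raise ValueError(
            f"initial fitness f0={f0} must lie in [0, {fmax}) "
            "(strictly below the target fitness)"
        )
    out = fl.copy()
    out.fitness[0] = f0
    return out


def shuffle_fitness(
    fl: FitnessLandscape,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> FitnessLandscape:
    """Randomly permute the fitness values over the genotypes.

    Destroys any fitness-to-distance correlation while preserving the
    fitness multiset exactly; the maximum is re-pinned to the target index
    so the result remains canonical.
    """
    rng = as_rng(seed)
    fitness = rng.permutation(fl.fitness)
    return FitnessLandscape(fl.shape, _pin_maximum(fitness))


def uniformize_ranks(fl: FitnessLandscape) -> FitnessLandscape:
    """Monotone transform making the fitness marginal uniform.

    The genotype of fitness rank ``r`` (0-based; ties broken by ascending
    genotype index) receives ``(r + 0.5) / N``, which keeps all values in
    the open interval ``(0, 1)`` and preserves the strict order of distinct
    fitnesses.  Accessibility and all path statistics depend only on the
    fitness order, so they are invariant under this transform.
    """
    n = fl.shape.N
    order = np.argsort(fl.fitness, kind="stable")
    out = np.empty(n, dtype=np.float64)
    out[order] = (np.arange(n, dtype=np.float64) + 0.5) / n
    return FitnessLandscape(fl.shape, out)


def write_landscape_tsv(
    fl: FitnessLandscape, path, alphabet: str | None = None
) -> None:
    """Write a ``sequence<TAB>fitness`` table covering all genotypes.

    Fitness is printed with :func:`repr` precision so the file round-trips
    exactly through :func:`flaccess.empirical.read_table`.
    """
    from .empirical import default_alphabet, sequence_strings

    alphabet = alphabet or default_alphabet(fl.shape.K)
    seqs = sequence_strings(fl.shape, alphabet)
    with open(path, "w") as fh:
        fh.write("sequence\tfitness\n")
        for s, f in zip(seqs, fl.fitness):
            fh.write(f"{s}\t{float(f)!r}\n")
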