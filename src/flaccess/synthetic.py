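"""Synthetic genotype-fitness tables with empirical-like structure.

Real genotype-fitness tables differ from House-of-Cards draws in two
ways this generator emulates: mean fitness falls off with Hamming
distance from the global optimum (a negative fitness-to-distance
correlation), and a small fraction of genotypes is missing (no fitness
could be measured).  A raw score mixes an i.i.d. uniform component with
a distance ramp,

    s_i = (1 - w) * u_i + w * (1 - d_i / L),

where ``d_i`` is the Hamming distance to the all-``K-1`` genotype and
``w`` in [0, 1] sets the correlation strength (0 = pure House-of-Cards,
1 = fitness fully determined by distance).  Scores are rank-uniformised
into fitness values, so ``w`` acts purely through the fitness order —
the only thing accessibility can see.  Finally a uniformly chosen
fraction ``m`` of non-target genotypes is deleted to mimic missing
measurements (the downstream pipeline restores them at the minimum
fitness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .empirical import EmpiricalTable, default_alphabet, sequence_strings
from .landscape import LandscapeShape, as_rng, distance_to_target

__all__ = ["SyntheticSpec", "generate_correlated", "write_fixture"]

#: Default missing fraction, mirroring the ~4% of genotypes without a
#: measurable fitness in the smaller of the two empirical data sets.
DEFAULT_MISSING = 0.04


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic table draw."""

    shape: LandscapeShape
    w: float = 0.6
    missing: float = DEFAULT_MISSING
    seed: int | None = None
    alphabet: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"correlation weight w must lie in [0, 1], got {self.w}")
        if not 0.0 <= self.missing < 1.0:
            raise ValueError(f"missing fraction must lie in [0, 1), got {self.missing}")


def generate_correlated(spec: SyntheticSpec) -> EmpiricalTable:
    """Draw one synthetic genotype-fitness table.

    Deterministic per seed.  The target (all-``K-1``) genotype is never
    deleted, so the global optimum always has a measured fitness.
    """
    shape = spec.shape
    rng = as_rng(spec.seed)
    u = rng.random(shape.N)
    d = distance_to_target(shape).astype(np.float64)
    scores = (1.0 - spec.w) * u + spec.w * (1.0 - d / shape.L)
    # rank-uniformise: ties (only possible at w=1) broken by index
    order = np.argsort(scores, kind="stable")
    fitness = np.empty(shape.N)
    fitness[order] = (np.arange(shape.N) + 0.5) / shape.N
    alphabet = spec.alphabet or default_alphabet(shape.K)
    seqs = sequence_strings(shape, alphabet)
    n_missing = int(round(spec.missing * shape.N))
    drop: set[int] = set()
    if n_missing:
        candidates = rng.permutation(shape.N - 1)  # target index N-1 excluded
        drop = set(candidates[:n_missing].tolist())
    records = {
        seqs[g]: float(fitness[g]) for g in range(shape.N) if g not in drop
    }
    return EmpiricalTable(alphabet=alphabet, L_full=shape.L, records=records)


def write_fixture(table: EmpiricalTable, path) -> None:
    """Write a table as ``sequence<TAB>fitness`` TSV (header included).

    Fitness values are printed with :func:`repr` precision, so reading
    the file back through :func:`flaccess.empirical.read_table` restores
    the records exactly.
    """
    with open(path, "w") as fh:
        fh.write("sequence\tfitness\n")
        for seq in sorted(table.records):
            fh.write(f"{seq}\t{table.records[seq]!r}\n")
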