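"""Shared fixtures and the independent path-enumeration oracle.

The oracle enumerates every strictly-fitness-increasing path by naive
recursive search over explicit neighbour lists and classifies its steps
one by one — it shares no code path with the memoized dynamic programs
it is used to check.
"""

from __future__ import annotations

import sys

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flaccess.landscape import (
    FitnessLandscape,
    LandscapeShape,
    generate_hoc,
    hamming_distance,
    neighbors,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

sys.setrecursionlimit(20000)


def enumerate_paths(
    fl: FitnessLandscape,
    mode: str = "all",
    start: int = 0,
    target: int | None = None,
    allowed: set | None = None,
) -> list[tuple[int, ...]]:
    """All admissible start -> target paths by brute-force recursion.

    ``allowed`` optionally restricts the traversal to a genotype subset
    (used for sub-landscape restriction checks).
    """
    shape = fl.shape
    tgt = shape.N - 1 if target is None else target
    f = fl.fitness
    out: list[tuple[int, ...]] = []

    def rec(g: int, acc: list[int]) -> None:
        if g == tgt:
            out.append(tuple(acc))
            return
        for h in neighbors(g, shape):
            h = int(h)
            if allowed is not None and h not in allowed:
                continue
            if f[h] <= f[g]:
                continue
            delta = hamming_distance(h, tgt, shape) - hamming_distance(g, tgt, shape)
            if mode == "no_backward" and delta > 0:
                continue
            if mode == "shortest_only" and delta != -1:
                continue
            rec(h, acc + [h])

    rec(start, [start])
    return out


def oracle_stats(fl: FitnessLandscape, mode: str = "all", start: int = 0):
    """Exact path statistics derived by classifying every enumerated step."""
    shape = fl.shape
    tgt = shape.N - 1
    paths = enumerate_paths(fl, mode, start=start)
    fwd = bwd = neu = 0
    hist: dict[tuple[int, int], int] = {}
    lengths: dict[int, int] = {}
    for p in paths:
        b = n = 0
        for a, c in zip(p, p[1:]):
            delta = hamming_distance(c, tgt, shape) - hamming_distance(a, tgt, shape)
            if delta == -1:
                fwd += 1
            elif delta == 1:
                bwd += 1
                b += 1
            else:
                neu += 1
                n += 1
        hist[(b, n)] = hist.get((b, n), 0) + 1
        ell = len(p) - 1
        lengths[ell] = lengths.get(ell, 0) + 1
    return {
        "n_paths": len(paths),
        "forward": fwd,
        "backward": bwd,
        "neutral": neu,
        "class_histogram": hist,
        "length_distribution": lengths,
    }


#: shapes used for randomized small-landscape checks (N <= 729)
ORACLE_SHAPES = [
    (2, 4, 40),
    (2, 5, 30),
    (3, 3, 40),
    (4, 2, 30),
    (3, 4, 30),
    (4, 3, 30),
    (3, 6, 10),
]


def random_landscapes(entropy: int = 2024):
    """Deterministic stream of (shape, landscape) pairs for the oracle suite."""
    for K, L, n in ORACLE_SHAPES:
        shape = LandscapeShape(K, L)
        for child in np.random.SeedSequence((entropy, K, L)).spawn(n):
            yield generate_hoc(shape, child)


@pytest.fixture(scope="session")
def small_landscape() -> FitnessLandscape:
    return generate_hoc(LandscapeShape(3, 3), 7)
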