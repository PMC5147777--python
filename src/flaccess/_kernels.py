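"""Numba kernels for traversals of the strictly-increasing-fitness DAG.

Admissible edges go from a genotype to a strictly fitter mutational
neighbour, optionally filtered by the step class relative to the target
genotype (all ``K-1`` characters, index ``N-1``):

* ``forward``          — Hamming distance to the target decreases by 1,
* ``backward``         — it increases by 1,
* ``distance_neutral`` — it is unchanged (impossible for ``K == 2``).

Pathway modes are encoded as integers: 0 = all steps, 1 = forward and
distance-neutral only (no backward mutations), 2 = forward only (shortest
pathways).  Because fitness strictly increases along every admissible
edge, the admissible subgraph is acyclic and single-visit traversals are
sound.
"""

import numpy as np
from numba import njit

MODE_ALL = 0
MODE_NO_BACKWARD = 1
MODE_SHORTEST = 2


@njit(cache=True)
def dfs_accessible(fitness, K, L, powers, mode, start, target):
    """True iff an admissible path start -> target exists (early exit).

    Iterative DFS with single-visit marking: reachability along the
    increasing-fitness DAG does not require backtracking.
    """
    n = fitness.shape[0]
    top = K - 1
    visited = np.zeros(n, dtype=np.uint8)
    stack = np.empty(n, dtype=np.int64)
    sp = 0
    stack[sp] = start
    sp += 1
    visited[start] = 1
    while sp > 0:
        sp -= 1
        g = stack[sp]
        fg = fitness[g]
        for p in range(L):
            pw = powers[p]
            d = (g // pw) % K
            d_off = 1 if d != top else 0
            for c in range(K):
                if c == d:
                    continue
                delta = (1 if c != top else 0) - d_off
                if mode == 1 and delta > 0:
                    continue
                if mode == 2 and delta != -1:
                    continue
                h = g + (c - d) * pw
                if visited[h] == 1:
                    continue
                if fitness[h] > fg:
                    if h == target:
                        return True
                    visited[h] = 1
                    stack[sp] = h
                    sp += 1
    return False


@njit(cache=True)
def reach_forward(fitness, K, L, powers, mode, start):
    """Mark genotypes reachable from ``start`` along admissible edges."""
    n = fitness.shape[0]
    top = K - 1
    visited = np.zeros(n, dtype=np.uint8)
    stack = np.empty(n, dtype=np.int64)
    sp = 0
    stack[sp] = start
    sp += 1
    visited[start] = 1
    while sp > 0:
        sp -= 1
        g = stack[sp]
        fg = fitness[g]
        for p in range(L):
            pw = powers[p]
            d = (g // pw) % K
            d_off = 1 if d != top else 0
            for c in range(K):
                if c == d:
                    continue
                delta = (1 if c != top else 0) - d_off
                if mode == 1 and delta > 0:
                    continue
                if mode == 2 and delta != -1:
                    continue
                h = g + (c - d) * pw
                if visited[h] == 0 and fitness[h] > fg:
                    visited[h] = 1
                    stack[sp] = h
                    sp += 1
    return visited


@njit(cache=True)
def reach_backward(fitness, K, L, powers, mode, target):
    """Mark genotypes from which ``target`` is reachable.

    Traverses admissible edges in reverse: from the current node ``x`` we
    step to any less-fit neighbour ``y`` whose edge ``y -> x`` passes the
    mode filter (the step class of ``y -> x`` is the negation of
    ``x -> y``'s distance change).
    """
    n = fitness.shape[0]
    top = K - 1
    visited = np.zeros(n, dtype=np.uint8)
    stack = np.empty(n, dtype=np.int64)
    sp = 0
    stack[sp] = target
    sp += 1
    visited[target] = 1
    while sp > 0:
        sp -= 1
        x = stack[sp]
        fx = fitness[x]
        for p in range(L):
            pw = powers[p]
            d = (x // pw) % K
            d_off = 1 if d != top else 0
            for c in range(K):
                if c == d:
                    continue
                # step class of y -> x where y differs from x at position p
                delta = d_off - (1 if c != top else 0)
                if mode == 1 and delta > 0:
                    continue
                if mode == 2 and delta != -1:
                    continue
                y = x + (c - d) * pw
                if visited[y] == 0 and fitness[y] < fx:
                    visited[y] = 1
                    stack[sp] = y
                    sp += 1
    return visited


@njit(cache=True)
def class_totals_float(fitness, K, L, powers, mode, start, target):
    """Path count and pooled step-class totals via float dynamic programming.

    Processes genotypes in decreasing fitness order; for each node the
    number of admissible paths to the target and the pooled forward /
    backward / distance-neutral step totals over those paths are
    accumulated from its strictly fitter neighbours.  float64 accumulators
    hold counts up to ~1e308 with 15-16 significant digits, which is ample
    for the ratios reported from large landscapes.

    Returns ``(n_paths, forward, backward, neutral)`` evaluated at
    ``start``.
    """
    n = fitness.shape[0]
    top = K - 1
    order = np.argsort(fitness)
    npaths = np.zeros(n, dtype=np.float64)
    fwd = np.zeros(n, dtype=np.float64)
    bwd = np.zeros(n, dtype=np.float64)
    neu = np.zeros(n, dtype=np.float64)
    npaths[target] = 1.0
    for i in range(n - 1, -1, -1):
        g = order[i]
        if g == target:
            continue
        fg = fitness[g]
        for p in range(L):
            pw = powers[p]
            d = (g // pw) % K
            d_off = 1 if d != top else 0
            for c in range(K):
                if c == d:
                    continue
                delta = (1 if c != top else 0) - d_off
                if mode == 1 and delta > 0:
                    continue
                if mode == 2 and delta != -1:
                    continue
                h = g + (c - d) * pw
                if fitness[h] > fg:
                    nh = npaths[h]
                    npaths[g] += nh
                    fwd[g] += fwd[h]
                    bwd[g] += bwd[h]
                    neu[g] += neu[h]
                    if delta < 0:
                        fwd[g] += nh
                    elif delta > 0:
                        bwd[g] += nh
                    else:
                        neu[g] += nh
    return npaths[start], fwd[start], bwd[start], neu[start]


@njit(cache=True)
def count_paths_float(fitness, K, L, powers, mode, start, target):
    """Number of admissible start -> target paths (float64 accumulator)."""
    n = fitness.shape[0]
    top = K - 1
    order = np.argsort(fitness)
    npaths = np.zeros(n, dtype=np.float64)
    npaths[target] = 1.0
    for i in range(n - 1, -1, -1):
        g = order[i]
        if g == target:
            continue
        fg = fitness[g]
        for p in range(L):
            pw = powers[p]
            d = (g // pw) % K
            d_off = 1 if d != top else 0
            for c in range(K):
                if c == d:
                    continue
                delta = (1 if c != top else 0) - d_off
                if mode == 1 and delta > 0:
                    continue
                if mode == 2 and delta != -1:
                    continue
                h = g + (c - d) * pw
                if fitness[h] > fg:
                    npaths[g] += npaths[h]
    return npaths[start]
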