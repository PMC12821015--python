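"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[frozenset[tuple[int, int, int]]]:
    """26-connected 3D components by explicit breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    neighbours = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        frontier = [start]
        seen[start] = True
        comp = set()
        while frontier:
            v = frontier.pop()
            comp.add(v)
            for dz, dy, dx in neighbours:
                w = (v[0] + dz, v[1] + dy, v[2] + dx)
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    frontier.append(w)
        comps.append(frozenset(comp))
    return comps


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    grid = np.concatenate([a, b])
    ecdf_a = (a[:, None] <= grid[None, :]).mean(axis=0)
    ecdf_b = (b[:, None] <= grid[None, :]).mean(axis=0)
    return float(np.abs(ecdf_a - ecdf_b).max())


def ks_exact_permutation(a, b) -> tuple[float, float]:
    """Two-sample KS by exhaustive enumeration of label assignments.

    Under the null every split of the pooled values into groups of sizes
    (n, m) is equally likely; p is the fraction of the C(n+m, n) splits
    whose D is at least the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d_obs = _ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n = a.size
    total = 0
    at_least = 0
    for idx in combinations(range(pooled.size), n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        d = _ks_statistic(pooled[mask], pooled[~mask])
        total += 1
        if d >= d_obs - 1e-12:
            at_least += 1
    return d_obs, at_least / total
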