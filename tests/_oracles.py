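"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths (and scipy's
clustering) so they can certify them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_jaccard(X: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity by explicit set arithmetic."""
    n = X.shape[0]
    sets = [set(np.flatnonzero(X[i]).tolist()) for i in range(n)]
    J = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = sets[i] | sets[j]
            J[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return J


def brute_average_linkage(D: np.ndarray) -> list[float]:
    """Naive agglomerative average linkage; returns sorted merge heights."""
    clusters: list[list[int]] = [[i] for i in range(D.shape[0])]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def brute_chain_blocks(times: list[float], window: float) -> list[list[int]]:
    """The unique partition of sorted onsets into gap-rule blocks.

    Enumerates all 2^(n-1) contiguous partitions and keeps the one where
    every within-block consecutive gap is <= window and every cut gap is
    > window; asserts uniqueness.
    """
    order = sorted(range(len(times)), key=lambda i: times[i])
    t = [times[i] for i in order]
    n = len(t)
    valid = []
    for cuts in itertools.product([0, 1], repeat=max(n - 1, 0)):
        ok = True
        for i, cut in enumerate(cuts):
            gap = t[i + 1] - t[i]
            if cut and gap <= window:
                ok = False
            if not cut and gap > window:
                ok = False
            if not ok:
                break
        if ok:
            blocks, current = [], [order[0]] if n else []
            for i, cut in enumerate(cuts):
                if cut:
                    blocks.append(current)
                    current = []
                current.append(order[i + 1])
            if current:
                blocks.append(current)
            valid.append(blocks)
    assert len(valid) == 1, "gap rule must give a unique partition"
    return valid[0]


def brute_vi_bits(x, y) -> float:
    """Variation of Information from explicit set intersections (base 2)."""
    x = list(x)
    y = list(y)
    n = len(x)
    groups_x = {lab: {i for i, v in enumerate(x) if v == lab} for lab in set(x)}
    groups_y = {lab: {i for i, v in enumerate(y) if v == lab} for lab in set(y)}
    vi = 0.0
    for gx in groups_x.values():
        for gy in groups_y.values():
            common = gx & gy
            if not common:
                continue
            p = len(common) / n
            vi -= p * (
                math.log2(len(common) / len(gy)) + math.log2(len(common) / len(gx))
            )
    return vi
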