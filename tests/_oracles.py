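"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: plain dict/loop
implementations of pairwise alignment DP, mutual information by contingency
counting, connected components by union-find, and a least-squares topology
fit for quartets.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum(a: str, b: str) -> float:
    return float(_B62[a, b])


def gotoh_local(a: str, b: str, first_gap: float = 12.0, extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps; a gap of length g costs
    first_gap + (g - 1) * extend. Returns the optimal score (floor 0)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = blosum(a[i - 1], b[j - 1]) + diag
            X[i][j] = max(M[i - 1][j] - first_gap, Y[i - 1][j] - first_gap,
                          X[i - 1][j] - extend)
            Y[i][j] = max(M[i][j - 1] - first_gap, X[i][j - 1] - first_gap,
                          Y[i][j - 1] - extend)
            best = max(best, M[i][j])
    return best


def gotoh_global(a: str, b: str, gap_open: float = 10.0, extend: float = 0.5) -> float:
    """Needleman-Wunsch with affine gaps; a gap of length g costs
    gap_open + g * extend (first gap character costs gap_open + extend)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    first = gap_open + extend
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - i * extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - j * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = blosum(a[i - 1], b[j - 1]) + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - first, Y[i - 1][j] - first,
                          X[i - 1][j] - extend)
            Y[i][j] = max(M[i][j - 1] - first, X[i][j - 1] - first,
                          Y[i][j - 1] - extend)
    return max(M[n][m], X[n][m], Y[n][m])


def mi_contingency(col_a: str, col_b: str) -> float:
    """MI (nats) of two alignment columns by direct contingency counting,
    excluding rows gapped in either column."""
    pairs = [(x, y) for x, y in zip(col_a, col_b) if x != "-" and y != "-"]
    n = len(pairs)
    if n == 0:
        return 0.0
    joint: dict[tuple[str, str], int] = {}
    ca: dict[str, int] = {}
    cb: dict[str, int] = {}
    for x, y in pairs:
        joint[(x, y)] = joint.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in joint.items():
        p = c / n
        mi += p * math.log(p / ((ca[x] / n) * (cb[y] / n)))
    return mi


def window_mean_helices(seq: str, kd: dict, window: int, threshold: float,
                        min_helix_len: int, merge_gap: int) -> list[tuple[int, int]]:
    """Direct per-position recomputation of the hydropathy helix rule."""
    n = len(seq)
    half = window // 2
    cand = [False] * n
    for i in range(half, n - half):
        vals = [kd[c] for c in seq[i - half : i + half + 1]]
        cand[i] = sum(vals) / window >= threshold
    # collect runs
    runs = []
    i = 0
    while i < n:
        if cand[i]:
            j = i
            while j + 1 < n and cand[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s + 1, e + 1) for s, e in merged if e - s + 1 >= min_helix_len]


def union_find_components(nodes: list[str], edges: list[tuple[str, str]]) -> set[frozenset]:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups: dict[str, set] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def best_quartet_split(labels: list[str], d: np.ndarray) -> frozenset:
    """Least-squares topology fit for 4 taxa: for each of the 3 unrooted
    topologies fit the 5 branch lengths to the 6 pairwise distances and pick
    the topology with smallest residual. Returns one cherry of the winner."""
    assert len(labels) == 4
    pairs = list(itertools.combinations(range(4), 2))
    y = np.array([d[i, j] for i, j in pairs])
    best = None
    for split in ([(0, 1), (2, 3)], [(0, 2), (1, 3)], [(0, 3), (1, 2)]):
        (a, b), (c, e) = split
        # columns: external branches x0..x3, internal branch x4
        A = np.zeros((6, 5))
        for row, (i, j) in enumerate(pairs):
            A[row, i] += 1
            A[row, j] += 1
            same = {i, j} in ({a, b}, {c, e})
            if not same:
                A[row, 4] = 1
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ sol - y) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, frozenset({labels[a], labels[b]}))
    return best[1]
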