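"""Independent reference implementations used only as test oracles.

Each oracle deliberately uses a different algorithm from the package
code it checks: Horn's quaternion method vs the SVD-based Kabsch
superposition, and an exhaustive recursion over alignment moves vs the
production dynamic-programming aligner.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def horn_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition via Horn's closed-form quaternion.

    Returns (rotation matrix, rmsd). Maximises trace(R S) by the
    largest eigenvector of the 4x4 N matrix built from the
    cross-covariance S.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    s = a.T @ b
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(n)
    q = v[:, np.argmax(w)]  # (w, x, y, z)
    qw, qx, qy, qz = q
    rot = np.array(
        [
            [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
            [2 * (qx * qy + qz * qw), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qx * qw)],
            [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx * qx + qy * qy)],
        ]
    )
    resid = a @ rot.T - b
    rmsd = math.sqrt(np.mean(np.sum(resid**2, axis=1)))
    return rot, rmsd


def affine_alignment_best_score(
    s1: str, s2: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Maximum global alignment score by exhaustive recursion.

    Branches over the three moves (substitute, gap-in-1, gap-in-2) at
    every position, carrying the previous move so that gap runs cost
    open + (L-1)*extend. Memoisation collapses shared suffixes without
    changing the maximum over the (unchanged) set of alignments.
    """
    n1, n2 = len(s1), len(s2)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == n1 and j == n2:
            return 0.0
        best = -math.inf
        if i < n1 and j < n2:
            best = max(best, matrix[s1[i], s2[j]] + rec(i + 1, j + 1, "M"))
        if i < n1:
            cost = gap_extend if state == "A" else gap_open
            best = max(best, -cost + rec(i + 1, j, "A"))
        if j < n2:
            cost = gap_extend if state == "B" else gap_open
            best = max(best, -cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


def affine_alignment_enumerate(
    s1: str, s2: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Literal enumeration of every alignment, scored whole (tiny n only)."""
    best = -math.inf
    stack = [(0, 0, "M", 0.0)]
    while stack:
        i, j, state, score = stack.pop()
        if i == len(s1) and j == len(s2):
            best = max(best, score)
            continue
        if i < len(s1) and j < len(s2):
            stack.append((i + 1, j + 1, "M", score + matrix[s1[i], s2[j]]))
        if i < len(s1):
            cost = gap_extend if state == "A" else gap_open
            stack.append((i + 1, j, "A", score - cost))
        if j < len(s2):
            cost = gap_extend if state == "B" else gap_open
            stack.append((i, j + 1, "B", score - cost))
    return best


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random unrooted binary tree and its exact additive distances.

    Built by joining random pairs with uniform branch lengths; returns
    (taxa, distance matrix, bipartitions as frozensets normalised away
    from the alphabetically first taxon).
    """
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    # adjacency representation with explicit internal nodes
    next_id = n_taxa
    edges: dict[tuple[int, int], float] = {}
    pool = list(range(n_taxa))
    while len(pool) > 3:
        i = int(rng.integers(len(pool)))
        a = pool.pop(i)
        j = int(rng.integers(len(pool)))
        b = pool.pop(j)
        parent = next_id
        next_id += 1
        edges[(parent, a)] = float(rng.uniform(0.05, 1.0))
        edges[(parent, b)] = float(rng.uniform(0.05, 1.0))
        pool.append(parent)
    center = next_id
    next_id += 1
    for leftover in pool:
        edges[(center, leftover)] = float(rng.uniform(0.05, 1.0))

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def leaf_distances(start: int) -> dict[int, float]:
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    dm = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = leaf_distances(i)
        for j in range(n_taxa):
            dm[i, j] = dist[j]

    # bipartitions: remove each internal edge, collect one side's leaves
    all_leaves = frozenset(taxa)
    splits = set()
    for (u, v) in edges:
        side = set()
        stack = [v]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x < n_taxa:
                side.add(taxa[x])
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side_f = frozenset(side)
        if taxa[0] in side_f:
            side_f = all_leaves - side_f
        if 1 < len(side_f) < n_taxa - 1:
            splits.add(side_f)
    return taxa, dm, splits
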