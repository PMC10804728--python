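"""Independent brute-force enumerators for the texture matrices.

Deliberately naive (triple loops, BFS) and written against the matrix
definitions only, so they share no code with the optimized implementation.
``levels`` arrays use 0 for outside-mask voxels and 1..Ng inside.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np

ALL_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


def glcm_bf(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for k in range(shape[0]):
        for j in range(shape[1]):
            for i in range(shape[2]):
                a = levels[k, j, i]
                if a == 0:
                    continue
                q = (k + direction[0], j + direction[1], i + direction[2])
                if _inside(shape, q):
                    b = levels[q]
                    if b > 0:
                        mat[a - 1, b - 1] += 1
                        mat[b - 1, a - 1] += 1
    return mat


def glrlm_bf(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    shape = levels.shape
    longest = sum(shape)
    mat = np.zeros((ng, longest))
    d = np.asarray(direction)
    starts = [
        p for p in product(range(shape[0]), range(shape[1]), range(shape[2]))
        if not _inside(shape, tuple(np.asarray(p) - d))
    ]
    for start in starts:
        seq = []
        p = np.asarray(start)
        while _inside(shape, tuple(p)):
            seq.append(levels[tuple(p)])
            p = p + d
        run_val, run_len = 0, 0
        for v in seq + [0]:
            if v == run_val:
                run_len += 1
            else:
                if run_val > 0:
                    mat[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, 1
    nz = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : nz[-1] + 1] if nz.size else mat[:, :1]


def _zones_bf(levels: np.ndarray):
    """26-connected constant-level zones: list of (level, voxel list)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in product(range(shape[0]), range(shape[1]), range(shape[2])):
        if levels[p] == 0 or seen[p]:
            continue
        level = levels[p]
        members = []
        queue = deque([p])
        seen[p] = True
        while queue:
            cur = queue.popleft()
            members.append(cur)
            for d in ALL_26:
                q = tuple(np.asarray(cur) + d)
                if _inside(shape, q) and not seen[q] and levels[q] == level:
                    seen[q] = True
                    queue.append(q)
        zones.append((level, members))
    return zones


def glszm_bf(levels: np.ndarray, ng: int) -> np.ndarray:
    zones = _zones_bf(levels)
    if not zones:
        return np.zeros((ng, 1))
    max_size = max(len(m) for _, m in zones)
    mat = np.zeros((ng, max_size))
    for level, members in zones:
        mat[level - 1, len(members) - 1] += 1
    return mat


def _taxicab_distance_bf(mask: np.ndarray) -> np.ndarray:
    """City-block distance to outside the mask (border voxel = 1), by BFS."""
    shape = mask.shape
    dist = np.full(shape, np.inf)
    queue = deque()
    for p in product(range(shape[0]), range(shape[1]), range(shape[2])):
        if not mask[p]:
            continue
        on_border = False
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = tuple(np.asarray(p) + d)
            if not _inside(shape, q) or not mask[q]:
                on_border = True
        if on_border:
            dist[p] = 1
            queue.append(p)
    while queue:
        cur = queue.popleft()
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = tuple(np.asarray(cur) + d)
            if _inside(shape, q) and mask[q] and dist[q] > dist[cur] + 1:
                dist[q] = dist[cur] + 1
                queue.append(q)
    return dist


def gldzm_bf(levels: np.ndarray, ng: int) -> np.ndarray:
    zones = _zones_bf(levels)
    if not zones:
        return np.zeros((ng, 1))
    dist = _taxicab_distance_bf(levels > 0)
    entries = [(lvl, int(min(dist[m] for m in members))) for lvl, members in zones]
    max_d = max(d for _, d in entries)
    mat = np.zeros((ng, max_d))
    for level, d in entries:
        mat[level - 1, d - 1] += 1
    return mat


def ngtdm_bf(levels: np.ndarray, ng: int):
    """Returns (s_i, n_i) arrays."""
    shape = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for p in product(range(shape[0]), range(shape[1]), range(shape[2])):
        a = levels[p]
        if a == 0:
            continue
        n[a - 1] += 1
        nbrs = []
        for d in ALL_26:
            q = tuple(np.asarray(p) + d)
            if _inside(shape, q) and levels[q] > 0:
                nbrs.append(levels[q])
        if nbrs:
            s[a - 1] += abs(a - float(np.mean(nbrs)))
    return s, n


def ngldm_bf(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    shape = levels.shape
    entries = []
    for p in product(range(shape[0]), range(shape[1]), range(shape[2])):
        a = levels[p]
        if a == 0:
            continue
        dep = 0
        for d in ALL_26:
            q = tuple(np.asarray(p) + d)
            if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(a)) <= alpha:
                dep += 1
        entries.append((a, dep))
    max_dep = max(d for _, d in entries) if entries else 0
    mat = np.zeros((ng, max_dep + 1))
    for a, dep in entries:
        mat[a - 1, dep] += 1
    return mat
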