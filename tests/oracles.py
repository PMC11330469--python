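"""Brute-force reference implementations of the texture matrices.

These are written for obviousness, not speed: explicit Python loops over
voxels, neighbors, lines and flood fills.  The production code must agree
with them exactly on every input.
"""

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def naive_gldm(levels, alpha=0):
    """(Ng, 27) dependence counts by looping over voxels and 26 neighbors."""
    mask = levels > 0
    Ng = int(levels.max())
    mat = np.zeros((Ng, 27), dtype=np.int64)
    for p in np.argwhere(mask):
        dep = 0
        for off in OFFSETS_26:
            q = tuple(p + off)
            if _inside(levels.shape, q) and mask[q]:
                if abs(int(levels[tuple(p)]) - int(levels[q])) <= alpha:
                    dep += 1
        mat[levels[tuple(p)] - 1, dep] += 1
    return mat


def naive_glrlm_one_direction(levels, direction):
    """(Ng, max_dim) run-length counts by walking every line voxel by voxel."""
    mask = levels > 0
    Ng = int(levels.max())
    shape = levels.shape
    mat = np.zeros((Ng, int(max(shape))), dtype=np.int64)
    d = np.asarray(direction)
    visited = np.zeros(shape, dtype=bool)
    for start in np.argwhere(mask):
        prev = tuple(start - d)
        # only start a run where the previous voxel cannot extend it
        if (
            _inside(shape, prev)
            and mask[prev]
            and levels[prev] == levels[tuple(start)]
        ):
            continue
        if visited[tuple(start)]:
            continue
        p = np.array(start)
        level = int(levels[tuple(start)])
        length = 0
        while _inside(shape, p) and mask[tuple(p)] and levels[tuple(p)] == level:
            visited[tuple(p)] = True
            length += 1
            p = p + d
        mat[level - 1, length - 1] += 1
    return mat


def naive_glszm(levels):
    """(Ng, max_size) zone counts by explicit 26-connected flood fill."""
    mask = levels > 0
    Ng = int(levels.max())
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p0 in np.argwhere(mask):
        p0 = tuple(p0)
        if seen[p0]:
            continue
        level = int(levels[p0])
        stack = [p0]
        seen[p0] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for off in OFFSETS_26:
                q = tuple(np.array(p) + off)
                if (
                    _inside(shape, q)
                    and not seen[q]
                    and mask[q]
                    and int(levels[q]) == level
                ):
                    seen[q] = True
                    stack.append(q)
        zones.append((level, size))
    if not zones:
        return np.zeros((Ng, 1), dtype=np.int64)
    max_size = max(s for _, s in zones)
    mat = np.zeros((Ng, max_size), dtype=np.int64)
    for level, size in zones:
        mat[level - 1, size - 1] += 1
    return mat
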