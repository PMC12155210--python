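"""Independent scalar oracles used to validate the vectorized implementations.

Everything here is deliberately written as plain-Python per-voxel logic with
its own connected-component search, kept free of any code from the package's
fast paths.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def cylinder_member_scalar(
    point_mm, origin_mm, normal, radius, above, below
) -> bool:
    """Strict-inequality membership of one point in an oblique cylinder."""
    dx = point_mm[0] - origin_mm[0]
    dy = point_mm[1] - origin_mm[1]
    dz = point_mm[2] - origin_mm[2]
    z = dx * normal[0] + dy * normal[1] + dz * normal[2]
    rho2 = dx * dx + dy * dy + dz * dz - z * z
    return rho2 < radius * radius and -below < z < above


def voxelize_scalar(shape, spacing, origin_mm, cyl_origin, normal, radius, above, below):
    """Per-voxel loop voxelization (slow, trusted)."""
    mask = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        x = origin_mm[0] + i * spacing[0]
        for j in range(shape[1]):
            y = origin_mm[1] + j * spacing[1]
            for k in range(shape[2]):
                z = origin_mm[2] + k * spacing[2]
                mask[i, j, k] = cylinder_member_scalar(
                    (x, y, z), cyl_origin, normal, radius, above, below
                )
    return mask


def _bfs_components(cells: set, neighbors) -> list[set]:
    comps = []
    todo = set(cells)
    while todo:
        seed = todo.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            c = queue.popleft()
            for n in neighbors(c):
                if n in todo:
                    todo.discard(n)
                    comp.add(n)
                    queue.append(n)
        comps.append(comp)
    return comps


def _neighbors8(c):
    i, j = c
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di or dj:
                yield (i + di, j + dj)


def _neighbors26(c):
    i, j, k = c
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di or dj or dk:
                    yield (i + di, j + dj, k + dk)


def agatston_weight_scalar(max_hu: float) -> int:
    if max_hu >= 400:
        return 4
    if max_hu >= 300:
        return 3
    if max_hu >= 200:
        return 2
    return 1


def score_scalar(values, spacing, roi_mask, calibration=0.001):
    """Trusted re-implementation of the full scoring chain.

    Returns (agatston, volume_mm3, mass_mg, n_lesions, n_valid_lesions).
    """
    sx, sy, sz = spacing
    nx, ny, nz = values.shape

    # per-slice 8-connected components of candidate voxels, area-filtered
    retained = set()
    for k in range(nz):
        cells = {
            (i, j)
            for i in range(nx)
            for j in range(ny)
            if roi_mask[i, j, k] and values[i, j, k] >= 130.0
        }
        for comp in _bfs_components(cells, _neighbors8):
            if len(comp) * sx * sy >= 1.0 - 1e-9:
                retained.update((i, j, k) for (i, j) in comp)

    # 3D lesions by 26-connectivity
    lesions = _bfs_components(retained, _neighbors26)

    total_ag = 0.0
    total_vol = 0.0
    total_mass = 0.0
    n_valid = 0
    for lesion in lesions:
        ag = 0.0
        zs = {k for (_, _, k) in lesion}
        for k in zs:
            cells = {(i, j) for (i, j, kk) in lesion if kk == k}
            for comp in _bfs_components(cells, _neighbors8):
                max_hu = max(values[i, j, k] for (i, j) in comp)
                ag += len(comp) * sx * sy * agatston_weight_scalar(max_hu)
        vol = len(lesion) * sx * sy * sz
        mean_hu = sum(values[c] for c in lesion) / len(lesion)
        total_ag += ag
        total_vol += vol
        total_mass += calibration * mean_hu * vol
        if ag > 10.0:
            n_valid += 1
    return total_ag, total_vol, total_mass, len(lesions), n_valid
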