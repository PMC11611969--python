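"""Shared fixtures: mask constructors and independent brute-force oracles.

The oracles here (BFS flood fill, neighborhood median, ellipsoid voxel
count) are deliberately naive re-derivations used to check the package's
vectorized implementations; they never call into the code under test.
"""

from collections import deque

import numpy as np
import pytest

from mslesion.io_volumes import BinaryMask, LabelMap, VolumeGrid


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    return BinaryMask(VolumeGrid(np.asarray(data, dtype=np.uint8), spacing, origin))


def empty_mask(shape=(8, 8, 8)) -> BinaryMask:
    return make_mask(np.zeros(shape, dtype=np.uint8))


@pytest.fixture
def mask_factory():
    return make_mask


def neighbor_offsets(connectivity: int):
    """All 3D index offsets adjacent under 6/18/26-connectivity."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                n = abs(dx) + abs(dy) + abs(dz)
                if n == 0:
                    continue
                if (connectivity == 6 and n == 1) or (connectivity == 18 and n <= 2) or connectivity == 26:
                    offs.append((dx, dy, dz))
    return offs


def floodfill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent BFS connected-component labeling oracle."""
    mask = np.asarray(mask, dtype=bool)
    offs = neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        labels[start] = nxt
        q = deque([start])
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offs:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= pi < si for pi, si in zip(p, mask.shape)) and mask[p] and not labels[p]:
                    labels[p] = nxt
                    q.append(p)
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Whether two labelings induce the same partition of the foreground."""
    if not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == len({p for p, _ in pairs}) == len({r for _, r in pairs})


def brute_median_filter(data: np.ndarray, kernel) -> np.ndarray:
    """O(n*k) neighborhood median with edge replication."""
    data = np.asarray(data, dtype=np.float64)
    out = np.empty_like(data)
    rx, ry, rz = (k // 2 for k in kernel)
    nx, ny, nz = data.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                vals = []
                for dx in range(-rx, rx + 1):
                    for dy in range(-ry, ry + 1):
                        for dz in range(-rz, rz + 1):
                            px = min(max(x + dx, 0), nx - 1)
                            py = min(max(y + dy, 0), ny - 1)
                            pz = min(max(z + dz, 0), nz - 1)
                            vals.append(data[px, py, pz])
                out[x, y, z] = np.median(vals)
    return out


def brute_ellipsoid_count(shape, spacing, center_vox, radii_mm) -> int:
    """Loop-based count of voxel centers inside an ellipsoid."""
    n = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                q = sum(
                    ((i - c) * s / r) ** 2
                    for i, c, s, r in zip((x, y, z), center_vox, spacing, radii_mm)
                )
                if q <= 1.0:
                    n += 1
    return n


@pytest.fixture
def floodfill_oracle():
    return floodfill_label


@pytest.fixture
def partition_check():
    return partitions_equal


@pytest.fixture
def brute_median():
    return brute_median_filter


def random_mask(rng, shape=(10, 10, 10), p=0.3) -> BinaryMask:
    return make_mask((rng.random(shape) < p).astype(np.uint8))


@pytest.fixture
def random_mask_factory():
    return random_mask
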