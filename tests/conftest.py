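"""Shared fixtures: small phantoms and oracle helpers.

The acceptance-scale phantom (10 grains, 4 chalky, 10 µm spacing) is
generated once per session and shared by the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import chalkct as ck


def match_labels_to_truth(est: ck.LabelMap, truth: ck.LabelMap) -> dict[int, int]:
    """Map each truth grain id to the estimated label covering most of it."""
    mapping = {}
    for tid in range(1, truth.n_labels + 1):
        vals = est.data[truth.data == tid]
        vals = vals[vals > 0]
        if vals.size == 0:
            raise AssertionError(f"truth grain {tid} not covered by any label")
        mapping[tid] = int(np.bincount(vals).argmax())
    return mapping


def bfs_flood_fill(mask: np.ndarray, seeds, connectivity: int) -> np.ndarray:
    """Brute-force breadth-first flood fill, the oracle for region_grow."""
    from collections import deque

    if connectivity == 6:
        offsets = [
            (dz, dy, dx)
            for dz, dy, dx in [(-1, 0, 0), (1, 0, 0), (0, -1, 0),
                               (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        ]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    out = np.zeros_like(mask, dtype=bool)
    queue = deque()
    for s in seeds:
        s = tuple(s)
        if mask[s] and not out[s]:
            out[s] = True
            queue.append(s)
    shape = mask.shape
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
                    and mask[nz, ny, nx] and not out[nz, ny, nx]):
                out[nz, ny, nx] = True
                queue.append((nz, ny, nx))
    return out


def union_find_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force union-find labeling, the oracle for label_grains."""
    parent: dict[tuple, tuple] = {}

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    voxels = list(zip(*np.nonzero(mask)))
    for v in voxels:
        parent[v] = v
    if connectivity == 6:
        offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) > (0, 0, 0)
        ]
    vset = set(voxels)
    for z, y, x in voxels:
        for dz, dy, dx in offsets:
            n = (z + dz, y + dy, x + dx)
            if n in vset:
                union((z, y, x), n)
    labels = np.zeros(mask.shape, dtype=np.int32)
    roots = {}
    for v in voxels:
        r = find(v)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[v] = roots[r]
    return labels


def random_blob_mask(rng: np.random.Generator, shape=(20, 20, 20), p=0.5) -> np.ndarray:
    """Random boolean grid; occasionally smoothed to get larger blobs."""
    mask = rng.random(shape) < p
    if rng.random() < 0.5:
        from scipy import ndimage

        mask = ndimage.gaussian_filter(mask.astype(float), 1.0) > p
    return mask


@pytest.fixture(scope="session")
def acceptance_phantom():
    """Noiseless 10-grain clay-embedded phantom with 4 chalky grains."""
    spec = ck.multigrain_spec(10, 4, rng_seed=7)
    volume, truth = ck.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def acceptance_segmentation(acceptance_phantom):
    _, volume, _ = acceptance_phantom
    return ck.segment_sample(volume)


@pytest.fixture(scope="session")
def small_phantom():
    """Three small grains (one chalky) for fast pipeline tests."""
    spec = ck.multigrain_spec(
        3, 1, spacing_mm=0.02, semi_axes_mm=(0.5, 0.24, 0.22),
        chalk_kind="centered_ball", rng_seed=3,
    )
    volume, truth = ck.generate_phantom(spec)
    return spec, volume, truth
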