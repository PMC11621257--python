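"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: fat counting
is a direct evaluation of the window predicate over nested loops, the
boundary-distance oracle is a nearest-neighbor search over background voxel
coordinates (KD-tree, not a distance transform), and the rank statistics
are computed from first principles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

import pulmofat as pf


# ---------------------------------------------------------------------------
# phantoms


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free 1 mm-isotropic phantom with one r = 10 mm fat sphere."""
    spec = pf.single_sphere_spec(10.0)
    return (spec, *pf.generate_phantom(spec))


@pytest.fixture(scope="session")
def scattered_phantom():
    """Default-geometry phantom with several randomly placed fat spheres."""
    spec = pf.default_spec(
        fat_set=tuple(pf.FatSphere(radius_mm=3.0) for _ in range(6)), seed=11
    )
    return (spec, *pf.generate_phantom(spec))


# ---------------------------------------------------------------------------
# oracles


def triple_loop_fat_count(image: pf.ImageVolume, lung: pf.LabelMask, window: pf.HUWindow) -> int:
    """Literal per-voxel loop applying the mask-and-window predicate."""
    n = 0
    nx, ny, nz = image.shape
    for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
        if lung.data[i, j, k] > 0 and window.lower <= image.data[i, j, k] <= window.upper:
            n += 1
    return n


def oracle_interior_distances(mask: np.ndarray, spacing) -> np.ndarray:
    """Distance (mm) from each foreground voxel center to the nearest
    background voxel center, by KD-tree nearest-neighbor search."""
    sp = np.asarray(spacing, float)
    fg_idx = np.argwhere(mask)
    bg_idx = np.argwhere(~mask)
    tree = cKDTree(bg_idx * sp)
    d, _ = tree.query(fg_idx * sp)
    return d


def oracle_subpleural_labels(mask: np.ndarray, spacing, depth_mm: float) -> np.ndarray:
    """Brute-force nearest-boundary classification: 1 = subpleural, 2 = deep,
    0 = background."""
    out = np.zeros(mask.shape, dtype=np.uint8)
    fg_idx = np.argwhere(mask)
    d = oracle_interior_distances(mask, spacing)
    sub = d <= depth_mm
    out[tuple(fg_idx[sub].T)] = 1
    out[tuple(fg_idx[~sub].T)] = 2
    return out


def oracle_kruskal_h(groups) -> float:
    """Hand-ranked Kruskal–Wallis H with tie correction, from the formula
    H = [12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N))."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g)
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts.astype(float) ** 3 - counts)
    denom = 1.0 - tie / (n_total**3 - n_total)
    return h / denom if denom > 0 else 0.0


def oracle_dunn_z(groups) -> dict[tuple[int, int], float]:
    """Dunn pairwise z from first principles on pooled mid-ranks."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    sorter = np.argsort(pooled, kind="stable")
    ranks = np.empty(n_total)
    sv = pooled[sorter]
    i = 0
    while i < n_total:
        j = i
        while j < n_total and sv[j] == sv[i]:
            j += 1
        ranks[sorter[i:j]] = (i + j + 1) / 2.0
        i = j
    per_group, start = [], 0
    for a in arrays:
        per_group.append(ranks[start : start + a.size])
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts.astype(float) ** 3 - counts)
    var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    out = {}
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var * (1 / arrays[i].size + 1 / arrays[j].size))
        out[(i, j)] = 0.0 if se == 0 else (per_group[i].mean() - per_group[j].mean()) / se
    return out


def random_blob_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """A random connected-ish foreground: union of a few random boxes/balls,
    guaranteed neither empty nor full."""
    from scipy.ndimage import binary_dilation

    mask = np.zeros(shape, dtype=bool)
    n_seeds = rng.integers(1, 4)
    for _ in range(n_seeds):
        c = [rng.integers(2, s - 2) for s in shape]
        mask[tuple(c)] = True
    mask = binary_dilation(mask, iterations=int(rng.integers(2, min(shape) // 3 + 2)))
    mask[0, :, :] = mask[-1, :, :] = False  # keep a background shell
    mask[:, 0, :] = mask[:, -1, :] = False
    mask[:, :, 0] = mask[:, :, -1] = False
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask
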