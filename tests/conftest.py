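"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy.spatial import cKDTree

from wpbscreen import FieldSpec

logging.getLogger("wpbscreen").setLevel(logging.ERROR)


def small_field_spec(**overrides) -> FieldSpec:
    """A fast 512x512 field holding ~25 nuclei, clean unless overridden."""
    defaults = dict(
        image_shape=(512, 512),
        n_nuclei=25,
        wpb_per_cell=8.0,
        noise_sigma=0.0,
        background=(50.0, 0.0, 0.0),
        wpb_intensity=1000.0,
        wpb_min_length_um=0.7,
        seed=0,
    )
    defaults.update(overrides)
    return FieldSpec(**defaults)


def match_objects(found_xy: np.ndarray, true_xy: np.ndarray, max_dist_px: float = 3.0):
    """Greedy nearest matching of found centroids to true centroids.

    Returns (matched mask over found, true index per found).
    """
    if len(true_xy) == 0 or len(found_xy) == 0:
        return np.zeros(len(found_xy), dtype=bool), np.zeros(len(found_xy), dtype=int)
    d, idx = cKDTree(true_xy).query(found_xy)
    return d < max_dist_px, idx


def bernsen_oracle(img: np.ndarray, radius: int, contrast_threshold: float) -> np.ndarray:
    """Direct per-pixel evaluation of the Bernsen rule (window clipped at
    image borders, circular footprint)."""
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    H, W = img.shape
    out = np.zeros((H, W), dtype=bool)
    offs = [
        (dr - radius, dc - radius)
        for dr in range(2 * radius + 1)
        for dc in range(2 * radius + 1)
        if fp[dr, dc]
    ]
    for i in range(H):
        for j in range(W):
            vals = [
                int(img[i + dr, j + dc])
                for dr, dc in offs
                if 0 <= i + dr < H and 0 <= j + dc < W
            ]
            mx, mn = max(vals), min(vals)
            midgray = (mx + mn) / 2.0
            if mx - mn < contrast_threshold:
                out[i, j] = midgray >= 128
            else:
                out[i, j] = img[i, j] >= midgray
    return out


def voronoi_oracle(centroids: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Brute-force nearest-centroid labels (no mesh), lowest label on ties."""
    H, W = shape
    out = np.zeros(shape, dtype=int)
    for r in range(H):
        for c in range(W):
            d2 = (centroids[:, 0] - r) ** 2 + (centroids[:, 1] - c) ** 2
            out[r, c] = int(np.argmin(d2)) + 1  # argmin takes first on ties
    return out


def median_polish_oracle(x: np.ndarray, n_iter: int = 5000, tol: float = 1e-13):
    """Independently coded long-run median polish (row/column sweeps only)."""
    resid = np.asarray(x, dtype=float).copy()
    for _ in range(n_iter):
        r = np.nanmedian(resid, axis=1)
        r = np.where(np.isnan(r), 0.0, r)
        resid = resid - r[:, None]
        c = np.nanmedian(resid, axis=0)
        c = np.where(np.isnan(c), 0.0, c)
        resid = resid - c[None, :]
        if np.abs(r).sum() + np.abs(c).sum() < tol:
            break
    return resid


def random_blob(rng: np.random.Generator, max_px: int = 200) -> np.ndarray:
    """A random 8-connected blob mask with <= max_px pixels."""
    size = int(rng.integers(8, 28))
    mask = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    mask[r, c] = True
    n_target = int(rng.integers(4, min(max_px, size * size // 2)))
    for _ in range(n_target):
        rr, cc = np.nonzero(mask)
        k = rng.integers(len(rr))
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        nr, nc = int(rr[k] + dr), int(cc[k] + dc)
        if 0 <= nr < size and 0 <= nc < size:
            mask[nr, nc] = True
    return mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170022)
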