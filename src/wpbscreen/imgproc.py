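"""Image-processing primitives composed by the segmentation pipelines.

The operations here mirror the classic ImageJ particle-analysis toolbox:
circular median filtering, rolling-ball / sliding-paraboloid background
subtraction, Bernsen local thresholding, distance-transform watershed
splitting of touching convex blobs, 8-connected component labeling with an
explicit grey-shade capacity, and area-based label filtering.

Conventions (used throughout the package):

* pixel centers sit at integer coordinates, row-major, 0-based;
* areas are pixel counts times ``pixel_size_um**2``;
* label rasters reserve 0 for background (or the Voronoi mesh).
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import rank, threshold_otsu
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import CapacityError, ParameterError

__all__ = [
    "LABEL_CAPACITY",
    "median_filter",
    "subtract_background",
    "to_8bit",
    "bernsen_threshold",
    "watershed_split",
    "label_components",
    "size_filter",
    "otsu_mask",
]

#: Maximum number of object labels a grey-shade label raster can encode.
#: A raster of ``b`` bits offers ``2**b`` grey shades; one (0) is reserved
#: for background / the separating mesh, leaving ``2**b - 1`` labels.
LABEL_CAPACITY = {8: 2**8 - 1, 16: 2**16 - 1}


def _circular_footprint(radius_px: int) -> np.ndarray:
    """Boolean disk footprint: pixels with ``dx**2 + dy**2 <= r**2``."""
    return disk(int(radius_px)).astype(bool)


def median_filter(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Median over a circular neighborhood; edges use nearest-pixel extension.

    Preserves the input dtype. ``radius_px`` must be >= 1.
    """
    if radius_px < 1:
        raise ParameterError(f"median radius must be >= 1, got {radius_px}")
    return ndi.median_filter(
        image, footprint=_circular_footprint(radius_px), mode="nearest"
    )


def _parabolic_opening(img: np.ndarray, radius: float) -> np.ndarray:
    """Grey-scale opening with a 1-D parabolic structuring element, applied
    sequentially along rows, columns and both diagonals.

    A parabola ``z = k**2 / (2 * radius)`` (the apex curvature of a ball of
    the given radius) is slid under the intensity profile in each direction;
    the upper envelope of the slid parabolas is the background estimate.
    """
    span = float(img.max()) - float(img.min())
    if span <= 0:
        return img.astype(float, copy=True)
    # beyond k_max the parabola exceeds the dynamic range and cannot touch
    k_max = int(np.ceil(np.sqrt(2.0 * radius * span))) + 1
    k = np.arange(-k_max, k_max + 1)
    s = -(k.astype(float) ** 2) / (2.0 * radius)
    bg = img.astype(float)
    # rows, columns
    bg = ndi.grey_opening(bg, structure=s[np.newaxis, :], mode="nearest")
    bg = ndi.grey_opening(bg, structure=s[:, np.newaxis], mode="nearest")
    # diagonals: the 1-px diagonal step is sqrt(2) long
    bg = _diag_parabolic_opening(bg, radius, (1, 1))
    bg = _diag_parabolic_opening(bg, radius, (1, -1))
    return bg


def _shift_slices(sr: int, sc: int, shape: tuple[int, int]):
    """Destination/source slice pair so that dst[r, c] aligns with
    src[r + sr, c + sc] (out-of-image positions dropped)."""
    H, W = shape
    dst = (slice(max(0, -sr), H - max(0, sr)), slice(max(0, -sc), W - max(0, sc)))
    src = (slice(max(0, sr), H - max(0, -sr)), slice(max(0, sc), W - max(0, -sc)))
    return dst, src


def _diag_parabolic_opening(a: np.ndarray, radius: float, step: tuple[int, int]):
    """Parabolic opening along a diagonal direction via shifted-slice
    min/max passes (positions outside the image are ignored)."""
    span = float(a.max()) - float(a.min())
    if span <= 0:
        return a.copy()
    step_len2 = float(step[0] ** 2 + step[1] ** 2)
    k_max = int(np.ceil(np.sqrt(2.0 * radius * span / step_len2))) + 1
    eroded = a.copy()
    for k in range(1, k_max + 1):
        pen = step_len2 * k * k / (2.0 * radius)
        for sgn in (1, -1):
            dst, src = _shift_slices(sgn * k * step[0], sgn * k * step[1], a.shape)
            view = eroded[dst]
            np.minimum(view, a[src] + pen, out=view)
    opened = eroded.copy()
    for k in range(1, k_max + 1):
        pen = step_len2 * k * k / (2.0 * radius)
        for sgn in (1, -1):
            dst, src = _shift_slices(sgn * k * step[0], sgn * k * step[1], a.shape)
            view = opened[dst]
            np.maximum(view, eroded[src] - pen, out=view)
    return opened


def subtract_background(
    image: np.ndarray, ball_radius_px: int = 1, sliding_paraboloid: bool = True
) -> np.ndarray:
    """Rolling-ball background subtraction, output clamped at 0.

    With ``sliding_paraboloid=True`` (the default used for the vWF channel)
    the background is the envelope of parabolas slid under the intensity
    landscape along rows, columns and diagonals; otherwise a plain rolling
    ball (`skimage.restoration.rolling_ball`) is used. Returns the input
    dtype, rounded if the input is integral.
    """
    if ball_radius_px < 1:
        raise ParameterError(f"rolling-ball radius must be >= 1, got {ball_radius_px}")
    img = np.asarray(image)
    if sliding_paraboloid:
        bg = _parabolic_opening(img, float(ball_radius_px))
    else:
        from skimage.restoration import rolling_ball

        bg = rolling_ball(img.astype(float), radius=ball_radius_px)
    out = np.clip(img.astype(float) - bg, 0.0, None)
    if np.issubdtype(img.dtype, np.integer):
        return np.round(out).astype(img.dtype)
    return out.astype(img.dtype)


def to_8bit(image: np.ndarray, max_value: int = 4095) -> np.ndarray:
    """Fixed linear 12-to-8-bit conversion: 0..max_value -> 0..255.

    Deterministic by design (no display-range dependence), so thresholds are
    comparable across images and plates.
    """
    img = np.clip(np.asarray(image, dtype=float), 0, max_value)
    return np.round(img * (255.0 / max_value)).astype(np.uint8)


def bernsen_threshold(
    image8: np.ndarray, window_radius_px: int = 15, contrast_threshold: float = 15
) -> np.ndarray:
    """Bernsen local thresholding of an 8-bit image.

    For each pixel, with ``mx``/``mn`` the max/min over a circular window
    (clipped at image borders): ``contrast = mx - mn`` and
    ``midgray = (mx + mn) / 2``. Low-contrast pixels
    (``contrast < contrast_threshold``) are foreground iff ``midgray >= 128``;
    otherwise the pixel is foreground iff its value ``>= midgray``.
    """
    if not (0 <= contrast_threshold <= 255):
        raise ParameterError(
            f"contrast threshold must be in [0, 255], got {contrast_threshold}"
        )
    img = np.asarray(image8)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ParameterError("Bernsen thresholding requires an 8-bit image")
        img = img.astype(np.uint8)
    fp = _circular_footprint(window_radius_px)
    mx = rank.maximum(img, fp).astype(np.int16)
    mn = rank.minimum(img, fp).astype(np.int16)
    contrast = mx - mn
    midgray = (mx + mn) / 2.0
    low = contrast < contrast_threshold
    fg = np.where(low, midgray >= 128, img >= midgray)
    return fg


def watershed_split(
    mask: np.ndarray, smooth_sigma: float = 1.0, min_distance_px: int = 5
) -> np.ndarray:
    """Split touching convex blobs by a distance-transform watershed.

    The Euclidean distance transform of the foreground is smoothed with a
    Gaussian (sigma in pixels) and its regional maxima (minimum separation
    ``min_distance_px``) seed a watershed. Separating lines are erased on
    the higher-label side of each basin boundary using the 8-neighborhood,
    so the resulting blobs are disconnected under the 8-connected labeling
    used downstream. A blob with a single maximum is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, smooth_sigma)
    comps, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    coords = peak_local_max(
        smooth, min_distance=min_distance_px, labels=comps, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    ws = watershed(-smooth, markers=markers, mask=mask)
    erase = np.zeros(mask.shape, dtype=bool)
    padded = np.pad(ws, 1, mode="edge")
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr:1 + dr + mask.shape[0], 1 + dc:1 + dc + mask.shape[1]]
            erase |= (nb > 0) & (nb < ws)
    out = mask.copy()
    out[erase] = False
    return out


def label_components(mask: np.ndarray, capacity: int = LABEL_CAPACITY[16]) -> np.ndarray:
    """8-connected component labeling, labels 1..N in raster-scan order of
    each component's first pixel; 0 is background.

    Raises :class:`CapacityError` when N exceeds ``capacity`` (the grey-shade
    budget of the destination raster; 255 for 8-bit, 65535 for 16-bit).
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > capacity:
        raise CapacityError(
            f"{n} components exceed the label capacity {capacity} "
            "(one grey shade is reserved for background)"
        )
    if n == 0:
        return lab.astype(np.int32)
    # enforce raster-scan numbering regardless of scipy's internal order
    flat = lab.ravel()
    uniq, first = np.unique(flat, return_index=True)
    nz = uniq != 0
    uniq, first = uniq[nz], first[nz]
    order = np.argsort(first, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[uniq[order]] = np.arange(1, n + 1, dtype=np.int32)
    return remap[lab]


def size_filter(
    labels: np.ndarray,
    min_area_um2: float | None,
    max_area_um2: float | None,
    pixel_size_um: float,
) -> np.ndarray:
    """Remove labeled components whose calibrated area falls outside
    ``[min_area_um2, max_area_um2]`` (inclusive bounds; either may be None).

    Surviving components keep their labels, so the operation is idempotent.
    """
    if pixel_size_um <= 0:
        raise ParameterError(f"pixel size must be > 0, got {pixel_size_um}")
    if min_area_um2 is not None and max_area_um2 is not None and min_area_um2 > max_area_um2:
        raise ParameterError(
            f"min area {min_area_um2} exceeds max area {max_area_um2}"
        )
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.copy()
    counts = np.bincount(labels.ravel())
    areas = counts * pixel_size_um**2
    bad = np.zeros(len(counts), dtype=bool)
    if min_area_um2 is not None:
        bad |= areas < min_area_um2
    if max_area_um2 is not None:
        bad |= areas > max_area_um2
    bad[0] = False
    out = labels.copy()
    out[bad[labels]] = 0
    return out


def otsu_mask(image: np.ndarray) -> np.ndarray:
    """Otsu global threshold -> boolean foreground mask.

    Returns an all-background mask for a constant image (no bimodality).
    """
    img = np.asarray(image)
    if img.min() == img.max():
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)
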