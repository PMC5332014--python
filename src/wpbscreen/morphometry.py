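"""Per-object morphometry in the style of ImageJ's particle analyzer.

For every labeled object the 24 classic features are computed: calibrated
area, raw-intensity statistics, centroid, crack-boundary perimeter,
best-fit-ellipse axes and orientation, circularity, Feret diameters by
rotating calipers over the convex hull of pixel corners, integrated
densities, and the derived shape descriptors AR, Round and Solidity.

Geometry conventions: pixel centers at integer (row, col) coordinates;
outlines and convex hulls are built on pixel corners (center +/- 0.5);
``X`` is the column direction, ``Y`` the row direction; angles are reported
in degrees in [0, 180), measured counter-clockwise from the +X axis in
display orientation (Y pointing down is flipped, matching how micrographs
are viewed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull

from .errors import ParameterError

__all__ = ["FEATURE_COLUMNS", "measure_objects", "pixel_corner_hull", "feret_brute_force"]

#: Table-order feature columns of a morphometry record.
FEATURE_COLUMNS = [
    "Area", "Mean", "StdDev", "Min", "Max", "X", "Y", "Perim.",
    "Major", "Minor", "Angle", "Circ.", "Feret", "IntDen", "Median",
    "RawIntDen", "Slice", "FeretX", "FeretY", "FeretAngle", "MinFeret",
    "AR", "Round", "Solidity",
]


def _corner_points(mask: np.ndarray) -> np.ndarray:
    """Unique pixel-corner points (x, y) of a mask's boundary pixels."""
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    boundary = mask & ~eroded
    rr, cc = np.nonzero(boundary)
    corners = np.empty((4 * len(rr), 2), dtype=float)
    for i, (dr, dc) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[i * len(rr):(i + 1) * len(rr), 0] = cc + dc  # x
        corners[i * len(rr):(i + 1) * len(rr), 1] = rr + dr  # y
    return np.unique(corners, axis=0)


def pixel_corner_hull(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex hull of the mask's pixel corners.

    Returns ``(vertices, hull_area)`` with vertices (x, y) in
    counter-clockwise order of the point set (as produced by Qhull) and the
    hull area in px^2.
    """
    pts = _corner_points(mask)
    hull = ConvexHull(pts)
    return pts[hull.vertices], float(hull.volume)


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _rotating_calipers_feret(P: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximum caliper distance over hull vertices by rotating calipers.

    ``P`` must be convex-hull vertices in CCW order. Returns the diameter
    and its two endpoints.
    """
    n = len(P)
    if n == 1:
        return 0.0, P[0], P[0]
    if n == 2:
        return float(np.hypot(*(P[1] - P[0]))), P[0], P[1]
    best_d2 = -1.0
    best = (P[0], P[0])
    j = 1
    for i in range(n):
        i2 = (i + 1) % n
        # advance the antipodal point while the triangle area grows
        while _cross(P[i], P[i2], P[(j + 1) % n]) > _cross(P[i], P[i2], P[j]):
            j = (j + 1) % n
        for a in (i, i2):
            d2 = float(np.sum((P[a] - P[j]) ** 2))
            if d2 > best_d2:
                best_d2 = d2
                best = (P[a], P[j])
    return float(np.sqrt(best_d2)), best[0], best[1]


def _min_caliper_width(P: np.ndarray) -> float:
    """Minimum width over all hull-edge directions (MinFeret)."""
    n = len(P)
    if n < 3:
        return 0.0
    best = np.inf
    for i in range(n):
        e = P[(i + 1) % n] - P[i]
        norm = np.hypot(e[0], e[1])
        if norm == 0:
            continue
        u = e / norm
        # width = max distance of any vertex from the edge line
        d = np.abs((P[:, 0] - P[i, 0]) * u[1] - (P[:, 1] - P[i, 1]) * u[0])
        best = min(best, float(d.max()))
    return best


def feret_brute_force(P: np.ndarray) -> float:
    """Maximum pairwise distance over hull points (independent oracle)."""
    d2 = np.sum((P[:, None, :] - P[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _fit_ellipse(rows: np.ndarray, cols: np.ndarray, area_px: int):
    """Second-central-moment ellipse, scaled so its area equals the object's.

    A 1/12 per-pixel variance term accounts for the unit-square pixel
    footprint, keeping single-pixel objects non-degenerate.
    """
    x = cols.astype(float)
    y = rows.astype(float)
    cxx = x.var() + 1.0 / 12.0
    cyy = y.var() + 1.0 / 12.0
    cxy = ((x - x.mean()) * (y - y.mean())).mean()
    half_tr = (cxx + cyy) / 2.0
    delta = np.sqrt(((cxx - cyy) / 2.0) ** 2 + cxy**2)
    l1, l2 = half_tr + delta, max(half_tr - delta, 1e-12)
    major_raw, minor_raw = 4.0 * np.sqrt(l1), 4.0 * np.sqrt(l2)
    scale = np.sqrt(area_px / (np.pi * major_raw * minor_raw / 4.0))
    # orientation of the major axis; flip y for display convention
    if delta < 1e-12:
        angle = 0.0
    else:
        vx, vy = l1 - cyy, cxy
        if abs(vx) < 1e-12 and abs(vy) < 1e-12:
            vx, vy = cxy, l1 - cxx
        angle = np.degrees(np.arctan2(-vy, vx)) % 180.0
    return major_raw * scale, minor_raw * scale, angle


def _perimeter_px(mask: np.ndarray) -> int:
    """Crack-boundary perimeter: count of pixel edges exposed to background."""
    padded = np.pad(mask, 1)
    per = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        per += int((padded & ~np.roll(padded, shift, axis=axis)).sum())
    return per


def measure_objects(
    labels: np.ndarray,
    intensity: np.ndarray,
    pixel_size_um: float,
    slice_index: int = 1,
) -> pd.DataFrame:
    """Measure every labeled object against the raw intensity image.

    Returns a DataFrame with one row per label (ascending), an
    ``object_label`` column, and the feature columns of
    :data:`FEATURE_COLUMNS`. An empty label map yields an empty frame with
    the full header.
    """
    labels = np.asarray(labels)
    intensity = np.asarray(intensity)
    if labels.shape != intensity.shape:
        raise ParameterError(
            f"label shape {labels.shape} != intensity shape {intensity.shape}"
        )
    if pixel_size_um <= 0:
        raise ParameterError(f"pixel size must be > 0, got {pixel_size_um}")
    ps = float(pixel_size_um)
    n = int(labels.max())
    records: list[dict] = []
    if n > 0:
        slices = ndi.find_objects(labels)
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            if sl is None:
                continue
            sub = labels[sl] == lab
            vals = intensity[sl][sub].astype(float)
            rr, cc = np.nonzero(sub)
            rr = rr + sl[0].start
            cc = cc + sl[1].start
            area_px = int(sub.sum())
            area = area_px * ps**2
            mean = float(vals.mean())
            perim_px = _perimeter_px(sub)
            perim = perim_px * ps
            major_px, minor_px, angle = _fit_ellipse(rr, cc, area_px)
            hull_pts, hull_area_px = pixel_corner_hull(sub)
            hull_pts = hull_pts + np.array([sl[1].start, sl[0].start], dtype=float)
            feret_px, p1, p2 = _rotating_calipers_feret(hull_pts)
            min_feret_px = _min_caliper_width(hull_pts)
            # endpoint with the smaller y (then smaller x) is reported
            end = p1 if (p1[1], p1[0]) <= (p2[1], p2[0]) else p2
            other = p2 if end is p1 else p1
            feret_angle = (
                np.degrees(np.arctan2(-(other[1] - end[1]), other[0] - end[0])) % 180.0
            )
            circ = min(1.0, 4.0 * np.pi * area_px / perim_px**2) if perim_px else 1.0
            ar = major_px / minor_px if minor_px > 0 else np.inf
            records.append({
                "object_label": lab,
                "Area": area,
                "Mean": mean,
                "StdDev": float(vals.std(ddof=0)),
                "Min": float(vals.min()),
                "Max": float(vals.max()),
                "X": float(cc.mean()),
                "Y": float(rr.mean()),
                "Perim.": perim,
                "Major": major_px * ps,
                "Minor": minor_px * ps,
                "Angle": angle,
                "Circ.": circ,
                "Feret": feret_px * ps,
                "IntDen": area * mean,
                "Median": float(np.median(vals)),
                "RawIntDen": float(vals.sum()),
                "Slice": int(slice_index),
                "FeretX": float(end[0]),
                "FeretY": float(end[1]),
                "FeretAngle": feret_angle,
                "MinFeret": min_feret_px * ps,
                "AR": ar,
                "Round": 1.0 / ar if np.isfinite(ar) else 0.0,
                "Solidity": min(1.0, area_px / hull_area_px),
            })
    df = pd.DataFrame.from_records(records, columns=["object_label"] + FEATURE_COLUMNS)
    return df
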