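"""Synthetic high-content plates with known ground truth.

Emulates the imaging conditions of a confluent HUVEC monolayer screened at
40x on a spinning-disk confocal: 70-100 elliptical nuclei per field at a
nominal pixel size of 0.1615 um, with rod-shaped WPBs scattered inside
each cell's territory on the vWF channel. Only the nuclear and WPB
channels are synthesized — the trans-Golgi and membrane channels play no
part in the analysis.

Rendering choices that matter for the downstream morphometry:

* Nuclei are filled ellipses (no anti-aliasing); a configurable fraction
  of placements is allowed to touch a neighbor, exercising the watershed.
* WPBs are capsules (rectangles with semicircular caps, end-to-end length
  = the drawn length) rasterized at 4x supersampling and box-downsampled,
  giving stable sub-pixel lengths around the 1.5 um Feret cut.
* Rod intensity is uniform over the capsule (real WPBs show little
  internal texture at this resolution); noise is additive Gaussian
  clipped to the 12-bit range [0, 4095].
* Rods are placed so that the rod and both its endpoints stay a safe
  margin inside the owning nucleus's Voronoi territory, keeping the
  ground-truth cell assignment exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "PlateLayout",
    "generate_field",
    "generate_plate",
    "default_screen_layout",
]

MAX_DN = 4095  # 12-bit intensities stored in 16-bit containers


@dataclass
class FieldSpec:
    """Parameters of one synthetic field of view.

    Lengths are in micrometers; intensities in 12-bit data numbers. The
    WPB length distribution is lognormal with parameters
    ``wpb_length_um = (mu, sigma)`` of the log; ``background`` is
    ``(level, row_slope, col_slope)`` in DN and DN/px.
    """

    image_shape: tuple[int, int] = (1024, 1376)
    pixel_size_um: float = 0.1615
    n_nuclei: int = 85
    nucleus_axes_um: tuple[tuple[float, float], tuple[float, float]] = (
        (11.0, 16.0),
        (7.0, 10.0),
    )
    nucleus_intensity: float = 1500.0
    wpb_per_cell: float = 15.0  # Poisson mean
    wpb_length_um: tuple[float, float] = (0.18, 0.5)
    wpb_min_length_um: float = 0.4
    wpb_width_um: float = 0.35
    wpb_intensity: float = 1200.0
    wpb_min_gap_um: float = 0.15
    background: tuple[float, float, float] = (100.0, 0.0, 0.0)
    noise_sigma: float = 8.0
    touching_fraction: float = 0.10
    area_tol: float = 0.20  # relative rasterization tolerance on areas
    seed: int = 0
    # multiplicative perturbations (planted effects / controls)
    count_effect: float = 1.0
    length_effect: float = 1.0
    intensity_effect: float = 1.0
    max_attempts: int = 5000
    supersample: int = 4

    def validate(self) -> None:
        if min(self.image_shape) < 8:
            raise ParameterError("image shape too small")
        for name in ("pixel_size_um", "wpb_width_um", "wpb_min_length_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.n_nuclei < 0 or self.wpb_per_cell < 0:
            raise ParameterError("counts must be non-negative")
        for (lo, hi) in self.nucleus_axes_um:
            if lo <= 0 or hi < lo:
                raise ParameterError("nucleus axis ranges must be positive and ordered")
        if self.wpb_length_um[1] <= 0:
            raise ParameterError("lognormal sigma must be strictly positive")
        for val in (self.nucleus_intensity, self.wpb_intensity, self.background[0]):
            if not (0 <= val <= MAX_DN):
                raise ParameterError(f"intensity {val} outside [0, {MAX_DN}]")
        if self.noise_sigma < 0:
            raise ParameterError("noise sigma must be >= 0")
        for eff in (self.count_effect, self.length_effect, self.intensity_effect):
            if eff < 0:
                raise ParameterError("effects must be >= 0")


@dataclass
class GroundTruth:
    """What was actually drawn in a field.

    ``wpb_records`` is a DataFrame with one row per rod: ``cell`` (1-based
    nucleus index), centroid in um, true end-to-end length and analytic
    area in um, and total rendered intensity (foreground sum before
    background and noise). ``per_cell_counts[i]`` is the rod count of cell
    ``i+1`` and always sums to ``len(wpb_records)``.
    """

    nucleus_centroids_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    nucleus_areas_um2: np.ndarray = field(default_factory=lambda: np.empty(0))
    wpb_records: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_cell_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def check(self) -> None:
        n_cells = len(self.nucleus_centroids_um)
        if len(self.wpb_records):
            cells = self.wpb_records["cell"].to_numpy()
            if cells.min() < 1 or cells.max() > n_cells:
                raise ParameterError("WPB record references a non-existent cell")
        if self.per_cell_counts.sum() != len(self.wpb_records):
            raise ParameterError("per-cell counts do not sum to the rod count")


WPB_TRUTH_COLUMNS = [
    "cell", "centroid_row_um", "centroid_col_um",
    "length_um", "area_um2", "total_intensity",
]


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Rejection-sample nucleus centers, semi-axes (px) and orientations.

    Separation is judged on the directional radius of each ellipse along
    the center line (``r(phi) = a b / sqrt((b cos phi)^2 + (a sin phi)^2)``
    with ``phi`` the angle between the center line and the major axis):
    non-touching placements keep center distances above 1.02x the sum of
    the two directional radii; a ``touching_fraction`` of placements
    relaxes this to 0.85x so pairs of nuclei touch or slightly overlap
    (exercising the watershed).
    """
    H, W = spec.image_shape
    ps = spec.pixel_size_um
    centers: list[tuple[float, float]] = []
    semis: list[tuple[float, float]] = []
    angles: list[float] = []

    def dir_radius(a, b, angle, theta):
        phi = theta - angle
        return a * b / np.hypot(b * np.cos(phi), a * np.sin(phi))

    for _ in range(spec.n_nuclei):
        touch = rng.random() < spec.touching_fraction
        a = rng.uniform(*spec.nucleus_axes_um[0]) / 2.0 / ps
        b = rng.uniform(*spec.nucleus_axes_um[1]) / 2.0 / ps
        ang = rng.uniform(0, np.pi)
        placed = False
        for _ in range(spec.max_attempts):
            r = rng.uniform(a, H - 1 - a)
            c = rng.uniform(a, W - 1 - a)
            factor = 0.85 if touch else 1.02
            ok = True
            for (r2, c2), (a2, b2), ang2 in zip(centers, semis, angles):
                d = np.hypot(r - r2, c - c2)
                theta = np.arctan2(r - r2, c - c2)
                need = dir_radius(a, b, ang, theta) + dir_radius(a2, b2, ang2, theta)
                if d < factor * need:
                    ok = False
                    break
            if ok:
                centers.append((r, c))
                semis.append((a, b))
                angles.append(ang)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {len(centers) + 1}/{spec.n_nuclei}: "
                "field too dense for the requested nucleus count and size"
            )
    return np.array(centers), np.array(semis), np.array(angles)


def _render_ellipse(canvas, center, semi, angle, value):
    """Fill a rotated ellipse (pixel-center-inside test); returns px area."""
    H, W = canvas.shape
    a, b = semi
    r0 = max(int(np.floor(center[0] - a)), 0)
    r1 = min(int(np.ceil(center[0] + a)), H - 1)
    c0 = max(int(np.floor(center[1] - a)), 0)
    c1 = min(int(np.ceil(center[1] + a)), W - 1)
    rr = np.arange(r0, r1 + 1)[:, None] - center[0]
    cc = np.arange(c0, c1 + 1)[None, :] - center[1]
    u = cc * np.cos(angle) + rr * np.sin(angle)
    v = -cc * np.sin(angle) + rr * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[r0:r1 + 1, c0:c1 + 1][inside] = value
    return int(inside.sum())


def _render_capsule(canvas, center, angle, length_px, width_px, value, ss):
    """Add an anti-aliased capsule to ``canvas``; returns coverage sum (px).

    The capsule is a segment of length ``length_px - width_px`` dilated by
    ``width_px / 2`` (end-to-end extent = ``length_px``), rasterized on an
    ``ss``-times-finer grid and box-downsampled to per-pixel coverage.
    """
    H, W = canvas.shape
    half = max(length_px - width_px, 0.0) / 2.0
    d = np.array([np.sin(angle), np.cos(angle)])
    p0 = np.asarray(center) - half * d
    p1 = np.asarray(center) + half * d
    rad = width_px / 2.0
    r0 = max(int(np.floor(min(p0[0], p1[0]) - rad - 1)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + rad + 1)), H - 1)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - rad - 1)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + rad + 1)), W - 1)
    if r1 < r0 or c1 < c0:
        return 0.0
    h, w = r1 - r0 + 1, c1 - c0 + 1
    rr = r0 + (np.arange(h * ss) + 0.5) / ss - 0.5
    cc = c0 + (np.arange(w * ss) + 0.5) / ss - 0.5
    RR, CC = rr[:, None], cc[None, :]
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.hypot(RR - p0[0], CC - p0[1])
    else:
        t = ((RR - p0[0]) * seg[0] + (CC - p0[1]) * seg[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(RR - (p0[0] + t * seg[0]), CC - (p0[1] + t * seg[1]))
    cov = (dist <= rad).reshape(h, ss, w, ss).mean(axis=(1, 3))
    canvas[r0:r1 + 1, c0:c1 + 1] += value * cov
    return float(cov.sum())


def generate_field(spec: FieldSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one field: ``(nuclei_image, wpb_image, truth)``.

    Both images are uint16 rasters of 12-bit intensities. Identical specs
    (including the seed) produce bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    ps = spec.pixel_size_um
    nuc = np.zeros((H, W), dtype=float)
    wpb = np.zeros((H, W), dtype=float)

    truth = GroundTruth(
        wpb_records=pd.DataFrame(columns=WPB_TRUTH_COLUMNS),
        per_cell_counts=np.zeros(spec.n_nuclei, dtype=int),
    )
    if spec.n_nuclei > 0:
        centers, semis, angles = _place_nuclei(spec, rng)
        for (r, c), (a, b), ang in zip(centers, semis, angles):
            value = spec.nucleus_intensity * rng.uniform(0.85, 1.15)
            _render_ellipse(nuc, (r, c), (a, b), ang, value)
        truth.nucleus_centroids_um = centers * ps
        truth.nucleus_areas_um2 = np.pi * semis[:, 0] * semis[:, 1] * ps**2

        # distance to the nearest other centroid bounds the safe rod radius
        if len(centers) > 1:
            d = np.hypot(
                centers[:, None, 0] - centers[None, :, 0],
                centers[:, None, 1] - centers[None, :, 1],
            )
            np.fill_diagonal(d, np.inf)
            nn = d.min(axis=1)
        else:
            nn = np.array([float(min(H, W))])

        counts = rng.poisson(spec.wpb_per_cell * spec.count_effect, spec.n_nuclei)
        mu, sigma = spec.wpb_length_um
        width_px = spec.wpb_width_um / ps
        value = spec.wpb_intensity * spec.intensity_effect
        records = []
        gap_px = spec.wpb_min_gap_um / ps
        for i, (center, n_rods) in enumerate(zip(centers, counts)):
            placed_rods = 0
            placed_segs: list[tuple[np.ndarray, np.ndarray]] = []
            for _ in range(n_rods):
                L_um = max(
                    float(rng.lognormal(mu + np.log(spec.length_effect), sigma)),
                    spec.wpb_min_length_um,
                )
                L_px = L_um / ps
                ang = rng.uniform(0, np.pi)
                for _try in range(80):
                    rad = rng.uniform(0, max(nn[i] / 2.0 - L_px / 2.0 - 2.0, 1.0))
                    theta = rng.uniform(0, 2 * np.pi)
                    rc = center + rad * np.array([np.sin(theta), np.cos(theta)])
                    dvec = np.array([np.sin(ang), np.cos(ang)]) * L_px / 2.0
                    pts = [rc - dvec, rc, rc + dvec]
                    if not all(
                        1 <= p[0] <= H - 2 and 1 <= p[1] <= W - 2 for p in pts
                    ):
                        continue
                    if not _owned(pts, centers, i, margin_px=2.0):
                        continue
                    min_sep = width_px + gap_px
                    if all(
                        _segment_distance(pts[0], pts[2], q0, q1) >= min_sep
                        for q0, q1 in placed_segs
                    ):
                        cov = _render_capsule(
                            wpb, rc, ang, L_px, width_px, value, spec.supersample
                        )
                        eff_len = max(L_um, spec.wpb_width_um)
                        area_um2 = (
                            (eff_len - spec.wpb_width_um) * spec.wpb_width_um
                            + np.pi * (spec.wpb_width_um / 2.0) ** 2
                        )
                        records.append({
                            "cell": i + 1,
                            "centroid_row_um": rc[0] * ps,
                            "centroid_col_um": rc[1] * ps,
                            "length_um": eff_len,
                            "area_um2": area_um2,
                            "total_intensity": value * cov,
                        })
                        placed_segs.append((pts[0], pts[2]))
                        placed_rods += 1
                        break
            truth.per_cell_counts[i] = placed_rods
        if records:
            truth.wpb_records = pd.DataFrame.from_records(
                records, columns=WPB_TRUTH_COLUMNS
            )

    level, rslope, cslope = spec.background
    bg = (
        level
        + rslope * np.arange(H, dtype=float)[:, None]
        + cslope * np.arange(W, dtype=float)[None, :]
    )
    nuc += bg
    wpb += bg
    if spec.noise_sigma > 0:
        nuc += rng.normal(0.0, spec.noise_sigma, (H, W))
        wpb += rng.normal(0.0, spec.noise_sigma, (H, W))
    nuc = np.clip(np.round(nuc), 0, MAX_DN).astype(np.uint16)
    wpb = np.clip(np.round(wpb), 0, MAX_DN).astype(np.uint16)
    truth.check()
    return nuc, wpb, truth


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2-D segments."""
    def pt_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        return float(np.hypot(*(p - (a + t * ab))))

    def ccw(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    # proper intersection -> distance 0
    d1, d2 = ccw(p0, p1, q0), ccw(p0, p1, q1)
    d3, d4 = ccw(q0, q1, p0), ccw(q0, q1, p1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(
        pt_seg(q0, p0, p1), pt_seg(q1, p0, p1),
        pt_seg(p0, q0, q1), pt_seg(p1, q0, q1),
    )


def _owned(points, centers, idx, margin_px):
    """True when every point is nearest to centroid ``idx`` with a margin.

    The margin (px) keeps rods clear of the Voronoi midlines, so the
    rendered object can never intersect the 1-px mesh.
    """
    for p in points:
        d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
        own = d[idx]
        d_other = np.delete(d, idx)
        if len(d_other) and d_other.min() - own < margin_px:
            return False
    return True


# ---------------------------------------------------------------------------
# plates


@dataclass
class PlateLayout:
    """A 96-well layout: roles and planted multiplicative effects.

    ``well_roles`` maps 'A01'..'H12' to 'sample', 'negative_control' or
    'positive_control'; every well must appear exactly once.
    ``effect_map`` maps wells to dicts with any of the keys 'count',
    'length', 'intensity'.
    """

    well_roles: dict
    fields_per_well: int = 5
    effect_map: dict = field(default_factory=dict)
    rows: int = 8
    cols: int = 12

    def validate(self) -> None:
        from .plateio import all_wells, parse_well_id

        expected = set(all_wells())
        if set(self.well_roles) != expected:
            raise ParameterError("layout must assign exactly one role to each of the 96 wells")
        for w in self.well_roles:
            parse_well_id(w)
        allowed = {"sample", "negative_control", "positive_control"}
        bad = {r for r in self.well_roles.values() if r not in allowed}
        if bad:
            raise ParameterError(f"unknown well roles: {sorted(bad)}")
        if self.fields_per_well < 1:
            raise ParameterError("fields_per_well must be >= 1")


def default_screen_layout(
    fields_per_well: int = 5,
    pos_effects: dict | None = None,
    hit_wells: dict | None = None,
) -> PlateLayout:
    """Control layout emulating the screened plates: 8 negative-control
    wells (non-targeting siRNA) and 8 positive-control wells (vWF
    knockdown: WPB count x0.1, intensity x0.2), placed on diagonals so no
    plate row or column is dominated by controls (keeps the B-score median
    polish honest).

    ``hit_wells`` optionally plants sample-well effects, e.g.
    ``{"A03": {"count": 1.6}}``.
    """
    from .plateio import all_wells

    if pos_effects is None:
        pos_effects = {"count": 0.1, "intensity": 0.2}
    roles = {w: "sample" for w in all_wells()}
    neg = [f"{chr(65 + r)}{r + 1:02d}" for r in range(8)]
    pos = [f"{chr(65 + r)}{r + 5:02d}" for r in range(8)]
    for w in neg:
        roles[w] = "negative_control"
    for w in pos:
        roles[w] = "positive_control"
    effects = {w: dict(pos_effects) for w in pos}
    if hit_wells:
        for w, eff in hit_wells.items():
            if roles[w] != "sample":
                raise ParameterError(f"hit well {w} collides with a control")
            effects[w] = dict(eff)
    return PlateLayout(well_roles=roles, fields_per_well=fields_per_well,
                       effect_map=effects)


def field_seed(base_seed: int, well: str, fov: int) -> int:
    """Deterministic per-(well, field) seed derived from the plate seed."""
    from .plateio import parse_well_id

    r, c = parse_well_id(well)
    ss = np.random.SeedSequence([int(base_seed), r * 12 + c, int(fov)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_plate(layout: PlateLayout, base_spec: FieldSpec, wells=None):
    """Yield ``(well, fov, nuclei_image, wpb_image, truth)`` for a plate.

    Wells are generated in row-major order, fields 1..fields_per_well; the
    per-field seed is derived deterministically from ``base_spec.seed``,
    so any subset of wells (the ``wells`` argument) reproduces exactly the
    images it would get within the full plate. Effects from
    ``layout.effect_map`` multiply the base spec's WPB count, length and
    intensity parameters.
    """
    layout.validate()
    base_spec.validate()
    from .plateio import all_wells

    selected = all_wells() if wells is None else list(wells)
    for well in selected:
        eff = layout.effect_map.get(well, {})
        for fov in range(1, layout.fields_per_well + 1):
            spec = replace(
                base_spec,
                seed=field_seed(base_spec.seed, well, fov),
                count_effect=base_spec.count_effect * eff.get("count", 1.0),
                length_effect=base_spec.length_effect * eff.get("length", 1.0),
                intensity_effect=base_spec.intensity_effect * eff.get("intensity", 1.0),
            )
            nuc, wpb, truth = generate_field(spec)
            yield well, fov, nuc, wpb, truth
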