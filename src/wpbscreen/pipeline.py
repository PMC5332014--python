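"""End-to-end orchestration: field -> plate -> screen.

``process_field`` runs the two-part analysis on one field (nucleus
segmentation + influence zones, then WPB segmentation + morphometry);
``run_plate`` maps it over a plate manifest and writes the per-plate
result tables; ``run_screen`` turns replicate well-feature tables into
B scores, Z scores, assay QC and a ranked hit list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError, WpbScreenError
from .plateio import (
    PipelineConfig,
    PlateManifest,
    all_wells,
    parse_well_id,
    write_feature_file,
)
from .stats import (
    FEATURE_FOLDERS,
    WELL_FEATURES,
    WellFeatureVector,
    b_score_normalize,
    compute_well_features,
    hit_list,
    replicate_sd,
    z_prime,
    z_scores,
)
from .wpb import (
    assign_wpb_cell_ids,
    extract_wpb_features,
    render_qc_overlay,
    segment_wpbs,
)
from .zones import assign_nuclei_to_zones, influence_zones, segment_nuclei

__all__ = ["FieldResult", "PlateResult", "ScreenResult", "process_field",
           "run_plate", "run_screen", "well_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class FieldResult:
    well: str
    fov: int
    nucleus_labels: np.ndarray
    nucleus_table: pd.DataFrame
    zones: np.ndarray
    wpb_labels: np.ndarray
    features: pd.DataFrame
    cell_ids: pd.DataFrame
    n_cells: int


@dataclass
class PlateResult:
    plate_id: str
    well_features: pd.DataFrame           # one row per well, 4 feature columns
    features: pd.DataFrame                # all per-object rows
    nuc_features: pd.DataFrame
    cell_id_table: pd.DataFrame
    counts_log: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ScreenResult:
    scores: dict        # feature -> DataFrame(plate, well, role, raw, b_score, z per replicate, z)
    hits: dict          # feature -> ranked DataFrame
    z_prime: dict       # feature -> list per replicate
    replicate_sd: dict  # feature -> DataFrame(plate, well, sd)


def process_field(
    nuclei_img: np.ndarray,
    wpb_img: np.ndarray,
    config: PipelineConfig,
    plate: str = "",
    well: str = "",
    fov: int = 1,
) -> FieldResult:
    """Run both pipeline parts on one field of view."""
    nuc_labels, nuc_table = segment_nuclei(
        nuclei_img,
        pixel_size_um=config.pixel_size_um,
        median_radius_px=config.median_radius_px,
        area_bounds_um2=config.nucleus_area_bounds_um2,
    )
    if len(nuc_table) == 0:
        logger.warning("%s %s f%d: zero nuclei; skipping WPB analysis", plate, well, fov)
        empty = extract_wpb_features(
            np.zeros_like(nuc_labels), wpb_img, config.pixel_size_um,
            plate=plate, well=well, field=fov,
        )
        return FieldResult(well, fov, nuc_labels, nuc_table,
                           np.zeros_like(nuc_labels, dtype=np.uint16),
                           np.zeros_like(nuc_labels), empty,
                           pd.DataFrame(columns=["object_label", "cell_id"]), 0)
    centroids = nuc_table[["centroid_row", "centroid_col"]].to_numpy()
    zone_map = influence_zones(centroids, nuclei_img.shape)
    nuc_table = nuc_table.merge(
        assign_nuclei_to_zones(nuc_labels, zone_map), on="label", how="left"
    )
    wpb_labels = segment_wpbs(
        wpb_img,
        zone_map,
        pixel_size_um=config.pixel_size_um,
        contrast_threshold=config.bernsen_contrast,
        bernsen_window_radius_px=config.bernsen_window_radius_px,
        rolling_ball_radius_px=config.rolling_ball_radius_px,
        max_area_um2=config.wpb_max_area_um2,
    )
    cell_ids = assign_wpb_cell_ids(wpb_labels, zone_map)
    features = extract_wpb_features(
        wpb_labels, wpb_img, config.pixel_size_um,
        plate=plate, well=well, field=fov, cell_ids=cell_ids,
    )
    return FieldResult(well, fov, nuc_labels, nuc_table, zone_map,
                       wpb_labels, features, cell_ids, len(nuc_table))


def _cells_for_feature(result: FieldResult, mode: str) -> int:
    if mode == "wpb_cells":
        return int(result.cell_ids["cell_id"].nunique()) if len(result.cell_ids) else 0
    return result.n_cells


def run_plate(
    manifest: PlateManifest,
    config: PipelineConfig,
    out_dir=None,
    write_overlays: bool = False,
) -> PlateResult:
    """Analyze every field of a plate and aggregate per-well statistics.

    Per-field failures are logged and skipped; the plate fails only when
    every field fails. With ``out_dir`` set, writes the result CSVs
    (``<plate>_Results_Features.csv``, ``..._Results_Nuc_Features.csv``,
    ``..._Results_WBP_cell_ID.csv``), the per-feature 3-column screen
    files, zone label rasters and optional QC overlays.
    """
    plate = manifest.plate_id
    by_well: dict[str, list[FieldResult]] = {}
    n_fail = n_total = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for well, fov in manifest.well_fields():
        n_total += 1
        try:
            res = process_field(
                manifest.load(well, fov, "nuclei"),
                manifest.load(well, fov, "wpb"),
                config, plate=plate, well=well, fov=fov,
            )
        except WpbScreenError as exc:
            logger.error("%s %s f%d failed: %s", plate, well, fov, exc)
            n_fail += 1
            continue
        by_well.setdefault(well, []).append(res)
        if out_dir is not None:
            zone_dir = out_dir / "influzone"
            zone_dir.mkdir(exist_ok=True)
            tifffile.imwrite(
                zone_dir / f"{well}_f{fov}_influzone.tif", res.zones.astype(np.uint16)
            )
            if write_overlays:
                from matplotlib import image as mpimg

                ov_dir = out_dir / "overlay_vWF_RGB"
                ov_dir.mkdir(exist_ok=True)
                overlay = render_qc_overlay(
                    manifest.load(well, fov, "wpb"), res.wpb_labels
                )
                mpimg.imsave(ov_dir / f"{well}_f{fov}_overlay.png", overlay)
    if n_total and n_fail == n_total:
        raise InputError(f"all {n_total} fields of plate {plate} failed")

    feat_rows, nuc_rows, cid_rows, well_rows, log_rows = [], [], [], [], []
    for well, results in sorted(by_well.items()):
        results = sorted(results, key=lambda r: r.fov)
        tables = [r.features for r in results]
        counts = [_cells_for_feature(r, config.cellcount_mode) for r in results]
        vec = compute_well_features(
            tables, counts, feret_cut_um=config.feret_cut_um, well=well, plate=plate
        )
        well_rows.append(vec.as_dict())
        for r in results:
            feat_rows.append(r.features)
            nt = r.nucleus_table.copy()
            nt.insert(0, "Label", f"{well}_f{r.fov}")
            nuc_rows.append(nt)
            ct = r.cell_ids.copy()
            ct.insert(0, "Label", f"{well}_f{r.fov}")
            cid_rows.append(ct)
            log_rows.append({
                "well": well, "fov": r.fov, "n_nuclei": r.n_cells,
                "n_wpb": len(r.features),
            })
    features = pd.concat(feat_rows, ignore_index=True) if feat_rows else pd.DataFrame()
    nuc_features = pd.concat(nuc_rows, ignore_index=True) if nuc_rows else pd.DataFrame()
    cell_id_table = pd.concat(cid_rows, ignore_index=True) if cid_rows else pd.DataFrame()
    well_features = pd.DataFrame(well_rows)
    counts_log = pd.DataFrame(log_rows)
    result = PlateResult(plate, well_features, features, nuc_features,
                         cell_id_table, counts_log)
    if out_dir is not None:
        features.to_csv(out_dir / f"{plate}_Results_Features.csv", index=False)
        nuc_features.to_csv(out_dir / f"{plate}_Results_Nuc_Features.csv", index=False)
        cell_id_table.to_csv(out_dir / f"{plate}_Results_WBP_cell_ID.csv", index=False)
        well_features.to_csv(out_dir / f"{plate}_well_features.csv", index=False)
        counts_log.to_csv(out_dir / f"{plate}_counts_log.csv", index=False)
        for feat in WELL_FEATURES:
            folder = out_dir / FEATURE_FOLDERS[feat]
            folder.mkdir(exist_ok=True)
            write_feature_file(
                folder / f"{plate}.txt", plate,
                well_features["well"].tolist(), well_features[feat].tolist(),
            )
    return result


def well_matrix(df: pd.DataFrame, value_col: str) -> np.ndarray:
    """Arrange a (well, value) table as the 8x12 plate matrix (NaN = absent)."""
    mat = np.full((8, 12), np.nan)
    for _, row in df.iterrows():
        r, c = parse_well_id(row["well"])
        mat[r, c] = row[value_col]
    return mat


def run_screen(
    replicates: list[pd.DataFrame],
    well_roles: dict,
    config: PipelineConfig | None = None,
    annotations: dict | None = None,
) -> ScreenResult:
    """Screen-level statistics over replicate well-feature tables.

    Each replicate is a DataFrame with columns ``plate``, ``well`` and the
    four feature columns (the ``well_features`` of one replicate's plates,
    concatenated). Every plate is B-score normalized separately (controls
    included in the polish); Z scores are computed per replicate across
    all sample wells of the screen and averaged over replicates; Z' is
    computed per replicate from the raw control values; reproducibility is
    the per-well SD of the B scores across replicates.
    """
    if config is None:
        config = PipelineConfig()
    if not replicates:
        raise InputError("at least one replicate is required")
    for rep in replicates:
        missing = {"plate", "well", *WELL_FEATURES} - set(rep.columns)
        if missing:
            raise InputError(f"replicate table lacks columns {sorted(missing)}")
    roles_known = set(well_roles.values())
    if "negative_control" not in roles_known or "positive_control" not in roles_known:
        raise InputError("well roles must annotate negative and positive controls")

    scores, hits, zprimes, rep_sds = {}, {}, {}, {}
    for feat in WELL_FEATURES:
        per_rep_scores = []
        per_rep_b = []
        zp = []
        for rep in replicates:
            rows = []
            for plate_id, sub in rep.groupby("plate", sort=True):
                mat = well_matrix(sub, feat)
                b = b_score_normalize(mat)
                for _, row in sub.iterrows():
                    r, c = parse_well_id(row["well"])
                    rows.append({
                        "plate": plate_id, "well": row["well"],
                        "role": well_roles.get(row["well"], "sample"),
                        "raw": row[feat], "b_score": b[r, c],
                    })
            tab = pd.DataFrame(rows)
            tab["z"] = z_scores(tab["b_score"], tab["role"]).values
            per_rep_scores.append(tab)
            per_rep_b.append(tab.set_index(["plate", "well"])["b_score"])
            pos = tab.loc[tab["role"] == "positive_control", "raw"].dropna()
            neg = tab.loc[tab["role"] == "negative_control", "raw"].dropna()
            zp.append(z_prime(pos, neg))
        merged = per_rep_scores[0][["plate", "well", "role"]].copy()
        merged["raw"] = np.mean([t["raw"].values for t in per_rep_scores], axis=0)
        merged["b_score"] = np.mean([t["b_score"].values for t in per_rep_scores], axis=0)
        for i, t in enumerate(per_rep_scores, start=1):
            merged[f"z_rep{i}"] = t["z"].values
        merged["z"] = np.mean([t["z"].values for t in per_rep_scores], axis=0)
        scores[feat] = merged
        zprimes[feat] = zp
        key = merged.set_index(["plate", "well"])
        hits[feat] = hit_list(
            key["z"], key["role"], threshold=config.z_threshold,
            annotations=annotations,
        )
        if len(replicates) >= 2:
            aligned = pd.concat(per_rep_b, axis=1)
            sd = aligned.std(axis=1, ddof=1)
            rep_sds[feat] = sd.rename("sd").reset_index()
        else:
            rep_sds[feat] = pd.DataFrame(columns=["plate", "well", "sd"])
    return ScreenResult(scores=scores, hits=hits, z_prime=zprimes,
                        replicate_sd=rep_sds)
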