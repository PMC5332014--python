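"""WPB segmentation, feature extraction, cell assignment, QC overlay."""

import numpy as np
import pandas as pd
import pytest

from wpbscreen import (
    IntegrityError,
    assign_wpb_cell_ids,
    extract_wpb_features,
    influence_zones,
    render_qc_overlay,
    segment_wpbs,
)
from wpbscreen.synth import FieldSpec, generate_field, _render_capsule
from wpbscreen.wpb import WPB_TABLE_COLUMNS

from conftest import match_objects, small_field_spec

PS = 0.1615


def single_zone(shape):
    return np.ones(shape, dtype=np.uint16)


class TestSegmentWpbs:
    def test_flat_field_yields_no_objects(self):
        img = np.full((128, 128), 100, dtype=np.uint16)
        labels = segment_wpbs(img, single_zone(img.shape), PS)
        assert labels.max() == 0

    def test_synthetic_rod_count_recovered(self):
        spec = small_field_spec(seed=21)
        nuc, wpb, truth = generate_field(spec)
        from wpbscreen import segment_nuclei

        nlab, ntab = segment_nuclei(nuc, PS)
        zones = influence_zones(
            ntab[["centroid_row", "centroid_col"]].to_numpy(), wpb.shape
        )
        labels = segment_wpbs(wpb, zones, PS)
        n_true = len(truth.wpb_records)
        assert abs(labels.max() - n_true) <= 0.05 * n_true

    def test_large_blob_excluded_by_clump_filter(self):
        img = np.full((128, 128), 100.0)
        # a 12 um^2 blob: 12/0.1615^2 ~ 460 px, e.g. 21x22 px block
        img[50:71, 50:72] += 1500
        labels = segment_wpbs(img.astype(np.uint16), single_zone(img.shape), PS)
        assert labels.max() == 0

    def test_mesh_pixels_deleted_from_objects(self):
        img = np.full((64, 64), 100.0)
        img[30:33, 20:44] += 1500  # a bar crossing the future mesh
        zones = np.ones((64, 64), dtype=np.uint16)
        zones[:, 32] = 0
        zones[:, 33:] = 2
        labels = segment_wpbs(img.astype(np.uint16), zones, PS)
        assert labels.max() >= 2  # bar cut into per-zone pieces
        assert not ((labels > 0) & (zones == 0)).any()


class TestCellIds:
    def test_object_inside_zone_gets_that_id(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:8, 5:12] = 1
        zones = np.full((20, 20), 3, dtype=np.uint16)
        table = assign_wpb_cell_ids(labels, zones)
        assert table.loc[0, "cell_id"] == 3

    def test_straddling_object_raises_integrity_error(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4, 2:8] = 1
        zones = np.ones((10, 10), dtype=np.uint16)
        zones[:, 5:] = 2
        with pytest.raises(IntegrityError):
            assign_wpb_cell_ids(labels, zones)

    def test_all_means_integer_on_synthetic_field(self):
        spec = small_field_spec(seed=8)
        nuc, wpb, truth = generate_field(spec)
        from wpbscreen import segment_nuclei

        _nlab, ntab = segment_nuclei(nuc, PS)
        zones = influence_zones(
            ntab[["centroid_row", "centroid_col"]].to_numpy(), wpb.shape
        )
        labels = segment_wpbs(wpb, zones, PS)
        table = assign_wpb_cell_ids(labels, zones)  # raises on any non-integer
        assert len(table) == labels.max()
        assert (table["cell_id"] > 0).all()


class TestExtractFeatures:
    def test_constant_rod_raw_integrated_density(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[10, 3:13] = 1
        labels[11, 3:13] = 1
        labels[12, 3:13] = 1
        labels[9, 3:13] = 1  # 40 px rod
        img = np.full((20, 20), 1000.0)
        df = extract_wpb_features(labels, img, PS, well="B02", field=2)
        assert df.loc[0, "RawIntDen"] == 40 * 1000
        assert df.loc[0, "Label"] == "B02_f2"
        assert df.loc[0, "Slice"] == 2

    def test_known_length_rod_feret(self):
        canvas = np.zeros((64, 64))
        length_px = 2.0 / PS  # a 2.0 um rod
        _render_capsule(canvas, (32.0, 32.0), 0.3, length_px, 0.35 / PS, 1000.0, 4)
        img = np.clip(canvas + 100, 0, 4095).astype(np.uint16)
        labels = segment_wpbs(img, single_zone(img.shape), PS)
        assert labels.max() == 1
        df = extract_wpb_features(labels, img, PS)
        assert df.loc[0, "Feret"] == pytest.approx(2.0, abs=0.2)

    def test_empty_labels_give_empty_table_with_header(self):
        df = extract_wpb_features(np.zeros((10, 10), dtype=int), np.zeros((10, 10)), PS)
        assert len(df) == 0
        assert list(df.columns) == WPB_TABLE_COLUMNS

    def test_row_count_matches_cell_id_table(self):
        spec = small_field_spec(seed=13, n_nuclei=10, wpb_per_cell=5)
        nuc, wpb, _truth = generate_field(spec)
        from wpbscreen import segment_nuclei

        _nlab, ntab = segment_nuclei(nuc, PS)
        zones = influence_zones(
            ntab[["centroid_row", "centroid_col"]].to_numpy(), wpb.shape
        )
        labels = segment_wpbs(wpb, zones, PS)
        cid = assign_wpb_cell_ids(labels, zones)
        df = extract_wpb_features(labels, wpb, PS, cell_ids=cid)
        assert len(df) == len(cid)

    def test_intensity_from_original_not_subtracted_image(self):
        # doubling the background after segmentation changes Mean but not
        # the masks when the label raster is held fixed
        spec = small_field_spec(seed=2, n_nuclei=8, wpb_per_cell=4)
        nuc, wpb, _ = generate_field(spec)
        labels = segment_wpbs(wpb, single_zone(wpb.shape), PS)
        a = extract_wpb_features(labels, wpb, PS)
        brighter = np.clip(wpb.astype(int) + 200, 0, 4095).astype(np.uint16)
        b = extract_wpb_features(labels, brighter, PS)
        assert np.allclose(b["Mean"], a["Mean"] + 200)
        assert np.array_equal(a["Area"], b["Area"])


class TestOverlay:
    def test_empty_labels_leave_grayscale_unchanged(self, rng):
        img = rng.integers(0, 4096, (32, 32)).astype(np.uint16)
        rgb = render_qc_overlay(img, np.zeros((32, 32), dtype=int))
        assert (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all()

    def test_contours_are_red_boundary_pixels(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:12, 5:12] = 1
        img = np.full((20, 20), 500, dtype=np.uint16)
        rgb = render_qc_overlay(img, labels)
        red = (rgb[..., 0] == 255) & (rgb[..., 1] == 0) & (rgb[..., 2] == 0)
        assert red.sum() >= 4
        # contour pixels lie on the object's boundary (object minus interior)
        import scipy.ndimage as ndi

        interior = ndi.binary_erosion(labels > 0, np.ones((3, 3)))
        boundary = (labels > 0) & ~interior
        assert (red <= boundary).all()
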