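"""Per-well features, B scores, Z scores, Z', replicate SD, hit listing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wpbscreen import (
    DegenerateScaleError,
    ParameterError,
    b_score_normalize,
    compute_well_features,
    hit_list,
    median_polish,
    replicate_sd,
    z_prime,
    z_scores,
)

from conftest import median_polish_oracle


def toy_table(areas, ferets, rawintden=None):
    n = len(areas)
    return pd.DataFrame({
        "Area": areas,
        "Feret": ferets,
        "RawIntDen": rawintden if rawintden is not None else [100.0] * n,
    })


class TestWellFeatures:
    def test_number_fraction_above_length_cut(self):
        tab = toy_table([1, 1, 1, 1], [1.0, 2.0, 2.0, 1.2])
        vec = compute_well_features([tab], [10])
        assert vec.TotalFoVpercentWPBnr == pytest.approx(0.5)

    def test_area_fraction_above_length_cut(self):
        tab = toy_table([1, 1, 2], [1.0, 2.0, 2.0])
        vec = compute_well_features([tab], [10])
        assert vec.PercentWPBarea == pytest.approx(0.75)

    def test_wpb_per_cell_mean_over_fields(self):
        t1 = toy_table([1] * 10, [1.0] * 10)
        t2 = toy_table([1] * 20, [1.0] * 20)
        vec = compute_well_features([t1, t2], [5, 5])
        assert vec.TotalWPBnrPerCellNR == pytest.approx(3.0)  # mean(2, 4)

    def test_intensity_per_cell(self):
        tab = toy_table([1, 1], [1.0, 1.0], rawintden=[300.0, 700.0])
        vec = compute_well_features([tab], [4])
        assert vec.TotalWPBrawIntDenPerCellNR == pytest.approx(250.0)

    def test_degenerate_fields_excluded_not_zeroed(self):
        # an empty field says nothing about the length fractions
        empty = toy_table([], [])
        full = toy_table([1, 1], [2.0, 1.0])
        vec = compute_well_features([empty, full], [5, 5])
        assert vec.TotalFoVpercentWPBnr == pytest.approx(0.5)
        assert vec.n_fov_used["TotalFoVpercentWPBnr"] == 1
        # but it does say there are zero WPBs per cell in that field
        assert vec.TotalWPBnrPerCellNR == pytest.approx((0 + 0.4) / 2)

    def test_all_degenerate_gives_nan(self):
        vec = compute_well_features([toy_table([], [])], [0])
        assert np.isnan(vec.PercentWPBarea) and np.isnan(vec.TotalWPBnrPerCellNR)


class TestBScore:
    def test_exactly_additive_plate_scores_zero(self):
        row = np.arange(8)[:, None] * 3.0
        col = np.arange(12)[None, :] * -2.0
        plate = 10.0 + row + col
        assert np.allclose(b_score_normalize(plate), 0.0)

    def test_constant_shift_absorbed(self, rng):
        plate = rng.normal(0, 1, (8, 12))
        assert np.allclose(
            b_score_normalize(plate + 100.0), b_score_normalize(plate), atol=1e-9
        )

    def test_outlier_dominates_additive_plate(self):
        plate = (np.arange(4)[:, None] + np.arange(4)[None, :]).astype(float)
        plate += np.random.default_rng(1).normal(0, 0.01, (4, 4))
        plate[2, 3] += 50.0
        b = b_score_normalize(plate)
        assert np.unravel_index(np.abs(b).argmax(), b.shape) == (2, 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_residuals_match_long_run_polish(self, seed):
        rng = np.random.default_rng(seed)
        plate = rng.normal(0, 1, (8, 12))
        _, _, _, resid = median_polish(plate)
        oracle = median_polish_oracle(plate)
        assert np.abs(resid - oracle).max() < 1e-6

    def test_nan_wells_preserved(self, rng):
        plate = rng.normal(0, 1, (8, 12))
        plate[0, 0] = np.nan
        b = b_score_normalize(plate)
        assert np.isnan(b[0, 0]) and np.isfinite(np.delete(b.ravel(), 0)).all()

    def test_all_missing_plate_rejected(self):
        with pytest.raises(ParameterError):
            b_score_normalize(np.full((8, 12), np.nan))


class TestZScores:
    def _series(self, vals):
        v = pd.Series(vals)
        return v, pd.Series(["sample"] * len(vals))

    def test_median_sample_scores_zero(self):
        v, r = self._series([1, 2, 3, 4, 5])
        assert z_scores(v, r)[2] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # median 3, MAD 1 -> z(5) = 2 / 1.4826
        v, r = self._series([1, 2, 3, 4, 5])
        assert z_scores(v, r)[4] == pytest.approx(2 / 1.4826)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        v, r = self._series([1.0, 2.0, 4.0, 8.0, 9.0])
        base = z_scores(v, r)
        scaled = z_scores(a * v + b, r)
        assert np.allclose(base, scaled, atol=1e-8)

    def test_controls_excluded_from_location_scale(self):
        v = pd.Series([1, 2, 3, 4, 5, -100.0])
        r = pd.Series(["sample"] * 5 + ["positive_control"])
        z = z_scores(v, r)
        assert z[2] == pytest.approx(0.0)
        assert z[5] < -10

    def test_zero_mad_rejected(self):
        v, r = self._series([2, 2, 2, 2, 7])
        with pytest.raises(DegenerateScaleError):
            z_scores(v, r)


class TestZPrime:
    def test_closed_form_example(self):
        # sample SD exactly 5 for {95,100,105}: Z' = 1 - 3*10/100 = 0.7
        assert z_prime([95, 100, 105], [195, 200, 205]) == pytest.approx(0.7)

    def test_perfect_separation(self):
        assert z_prime([5.0, 5.0], [9.0, 9.0]) == pytest.approx(1.0)

    def test_wider_spread_decreases_score(self):
        tight = z_prime([95, 100, 105], [195, 200, 205])
        wide = z_prime([90, 100, 110], [195, 200, 205])
        assert wide < tight

    def test_equal_means_rejected(self):
        with pytest.raises(DegenerateScaleError):
            z_prime([1.0, 3.0], [2.0, 2.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            z_prime([1.0], [2.0, 3.0])


class TestReplicateSd:
    def test_identical_replicates_give_zero(self, rng):
        plate = rng.normal(0, 1, (8, 12))
        assert np.allclose(replicate_sd([plate, plate.copy()]), 0.0)

    def test_two_value_sample_sd(self):
        a = np.full((2, 2), 1.0)
        b = np.full((2, 2), 3.0)
        assert np.allclose(replicate_sd([a, b]), np.sqrt(2.0))

    def test_permutation_invariance(self, rng):
        reps = [rng.normal(0, 1, (8, 12)) for _ in range(3)]
        assert np.allclose(replicate_sd(reps), replicate_sd(reps[::-1]))

    def test_single_replicate_rejected(self):
        with pytest.raises(ParameterError):
            replicate_sd([np.zeros((8, 12))])


class TestHitList:
    def test_strict_threshold(self):
        z = pd.Series({"A02": 2.5, "A03": 1.9, "A04": 2.0})
        roles = pd.Series({"A02": "sample", "A03": "sample", "A04": "sample"})
        hits = hit_list(z, roles, threshold=2.0)
        assert list(hits["well"]) == ["A02"]

    def test_empty_when_nothing_exceeds(self):
        z = pd.Series({"A02": 0.5, "A03": -1.0})
        roles = pd.Series({"A02": "sample", "A03": "sample"})
        assert len(hit_list(z, roles)) == 0

    def test_controls_never_listed(self):
        z = pd.Series({"A02": 5.0, "A03": 4.0})
        roles = pd.Series({"A02": "positive_control", "A03": "sample"})
        hits = hit_list(z, roles)
        assert list(hits["well"]) == ["A03"]

    def test_annotations_attached_descending(self):
        z = pd.Series({"B02": 3.0, "C03": 4.5})
        roles = pd.Series({"B02": "sample", "C03": "sample"})
        hits = hit_list(z, roles, annotations={"B02": "DYRK4", "C03": "LMTK3"})
        assert list(hits["gene"]) == ["LMTK3", "DYRK4"]
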