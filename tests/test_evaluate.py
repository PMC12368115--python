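"""Ground-truth matching and detection metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from dhpsf.evaluate import (
    accuracy_stats,
    eligibility_filters,
    filter_z_window,
    match,
    metrics,
    sensitivity_vs_z,
    translation_correct,
)


def _table(xyz, frame=0, intensity=100.0):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return pd.DataFrame({
        "frame": frame, "x_nm": xyz[:, 0], "y_nm": xyz[:, 1],
        "z_nm": xyz[:, 2], "intensity": intensity,
    })


def _optimal_tp(det, tru, tol_xy, tol_z):
    """Maximum-cardinality one-to-one matching within tolerance."""
    d = det[["x_nm", "y_nm", "z_nm"]].to_numpy()
    t = tru[["x_nm", "y_nm", "z_nm"]].to_numpy()
    dxy = np.hypot(d[:, None, 0] - t[None, :, 0], d[:, None, 1] - t[None, :, 1])
    dz = np.abs(d[:, None, 2] - t[None, :, 2])
    ok = (dxy <= tol_xy) & (dz <= tol_z)
    big = 1e9
    cost = np.where(ok, np.sqrt(dxy ** 2 + dz ** 2), big)
    n = max(cost.shape)
    padded = np.full((n, n), big)
    padded[:cost.shape[0], :cost.shape[1]] = cost
    ri, ci = linear_sum_assignment(padded)
    return int(np.sum(padded[ri, ci] < big))


class TestMatch:
    def test_identical_tables_match_perfectly(self, rng):
        pts = rng.uniform(0, 5000, size=(20, 3))
        truth = _table(pts)
        report = match(truth, truth)
        assert report.n_tp == 20 and report.n_fp == 0 and report.n_fn == 0
        assert (report.pairs["d_3d_nm"] == 0).all()

    def test_one_truth_two_detections(self):
        truth = _table([[0, 0, 0]])
        det = _table([[10, 0, 0], [40, 0, 0]])
        report = match(det, truth)
        assert report.n_tp == 1 and report.n_fp == 1 and report.n_fn == 0
        assert report.pairs["d_3d_nm"].iloc[0] == pytest.approx(10.0)

    def test_same_frame_requirement(self):
        truth = _table([[0, 0, 0]], frame=0)
        det = _table([[0, 0, 0]], frame=1)
        assert match(det, truth, same_frame=True).n_tp == 0
        assert match(det, truth, same_frame=False).n_tp == 1

    def test_counts_are_consistent(self, rng):
        det = _table(rng.uniform(0, 2000, size=(8, 3)))
        tru = _table(rng.uniform(0, 2000, size=(11, 3)))
        report = match(det, tru)
        assert report.n_tp + report.n_fp == 8
        assert report.n_tp + report.n_fn == 11

    def test_greedy_close_to_optimal(self, rng):
        """Greedy assignment loses at most a small fraction of the optimal
        TP count over 1000 random 10x10 instances."""
        agree = 0
        trials = 1000
        for _ in range(trials):
            # realistic localisation errors: ~50 nm lateral, ~100 nm axial
            tru = _table(rng.uniform(0, 3000, size=(10, 3)))
            noise = rng.normal(0, [50.0, 50.0, 100.0], size=(10, 3))
            det = _table(tru[["x_nm", "y_nm", "z_nm"]].to_numpy() + noise)
            report = match(det, tru)
            optimal = _optimal_tp(det, tru, 250.0, 500.0)
            assert report.n_tp <= optimal
            agree += report.n_tp == optimal
        assert agree / trials >= 0.95

    def test_row_permutation_invariance(self, rng):
        tru = _table(rng.uniform(0, 2000, size=(12, 3)))
        det = _table(tru[["x_nm", "y_nm", "z_nm"]].to_numpy()
                     + rng.normal(0, 60, size=(12, 3)))
        base = metrics(match(det, tru))
        perm = metrics(match(det.sample(frac=1, random_state=1),
                             tru.sample(frac=1, random_state=2)))
        assert base == perm


class TestMetrics:
    def test_arithmetic(self):
        report = match(_table(np.zeros((1, 3))), _table(np.zeros((1, 3))))
        report.n_tp, report.n_fp, report.n_fn = 9, 1, 1
        m = metrics(report)
        assert m.precision == pytest.approx(0.9)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.jaccard == pytest.approx(9 / 11)

    def test_perfect_detection(self):
        pts = np.arange(30).reshape(10, 3) * 100.0
        m = metrics(match(_table(pts), _table(pts)))
        assert m == (1.0, 1.0, 1.0)

    def test_empty_everything_flags_undefined(self):
        report = match(_table(np.empty((0, 3))), _table(np.empty((0, 3))))
        m = metrics(report)
        assert np.isnan(m.precision) and np.isnan(m.sensitivity) \
            and np.isnan(m.jaccard)

    def test_bounds_and_jaccard_inequality(self, rng):
        for _ in range(50):
            det = _table(rng.uniform(0, 1000, size=(rng.integers(1, 8), 3)))
            tru = _table(rng.uniform(0, 1000, size=(rng.integers(1, 8), 3)))
            m = metrics(match(det, tru))
            for v in m:
                assert 0.0 <= v <= 1.0
            assert m.jaccard <= min(m.precision, m.sensitivity) + 1e-12


class TestAccuracyStats:
    def test_constant_distances(self):
        tru = _table([[0, 0, 0], [1000, 0, 0]])
        det = _table([[30, 0, 0], [1030, 0, 0]])
        stats = accuracy_stats(match(det, tru))
        assert stats["median_d_xy_nm"] == pytest.approx(30.0)
        assert stats["median_d_3d_nm"] == pytest.approx(30.0)

    def test_median_of_axial_distances(self):
        tru = _table([[0, 0, 0], [1000, 0, 0], [2000, 0, 0]])
        det = _table([[0, 0, 1], [1000, 0, 2], [2000, 0, 3]])
        stats = accuracy_stats(match(det, tru))
        assert stats["median_d_z_nm"] == pytest.approx(2.0)

    def test_empty_report_rejected(self):
        report = match(_table(np.empty((0, 3))), _table(np.empty((0, 3))))
        with pytest.raises(ValueError):
            accuracy_stats(report)


class TestSensitivityVsZ:
    def test_uniform_detection_flat_profile(self, rng):
        pts = np.column_stack([
            rng.uniform(0, 1000, 300), rng.uniform(0, 1000, 300),
            rng.uniform(-2000, 2000, 300)])
        tru = _table(pts)
        profile = sensitivity_vs_z(match(tru, tru), tru, bin_nm=500.0)
        assert (profile["sensitivity"] == 1.0).all()

    def test_axially_blind_detector(self, rng):
        z = rng.uniform(-2000, 2000, 400)
        pts = np.column_stack([rng.uniform(0, 500, 400) * 0, z * 0, z])
        tru = _table(pts)
        det = _table(pts[np.abs(z) <= 1500])
        profile = sensitivity_vs_z(match(det, tru), tru, bin_nm=250.0)
        outer = profile[np.abs(profile["z_center_nm"]) > 1750]
        inner = profile[np.abs(profile["z_center_nm"]) < 1250]
        assert (outer["sensitivity"] == 0.0).all()
        assert (inner["sensitivity"] == 1.0).all()

    def test_windowed_jaccard_equals_manual_filtering(self, rng):
        tru = _table(np.column_stack([
            rng.uniform(0, 3000, 200), rng.uniform(0, 3000, 200),
            rng.uniform(-2000, 2000, 200)]))
        det = _table(tru[["x_nm", "y_nm", "z_nm"]].to_numpy()
                     + rng.normal(0, 40, size=(200, 3)))
        window = (-1500.0, 1500.0)
        auto = metrics(match(filter_z_window(det, window),
                             filter_z_window(tru, window)))
        man_det = det[(det["z_nm"] >= -1500) & (det["z_nm"] <= 1500)]
        man_tru = tru[(tru["z_nm"] >= -1500) & (tru["z_nm"] <= 1500)]
        manual = metrics(match(man_det.reset_index(drop=True),
                               man_tru.reset_index(drop=True)))
        assert auto == manual


class TestTranslationCorrect:
    def test_constant_offset_inverted_exactly(self, rng):
        tru = _table(rng.uniform(0, 2000, size=(30, 3)))
        offset = np.array([10.0, -5.0, 20.0])
        det = _table(tru[["x_nm", "y_nm", "z_nm"]].to_numpy() + offset)
        corrected = translation_correct(det, match(det, tru))
        report = match(corrected, tru)
        stats = accuracy_stats(report)
        assert stats["median_d_3d_nm"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_offset_is_identity(self, rng):
        tru = _table(rng.uniform(0, 2000, size=(10, 3)))
        corrected = translation_correct(tru, match(tru, tru))
        np.testing.assert_allclose(
            corrected[["x_nm", "y_nm", "z_nm"]], tru[["x_nm", "y_nm", "z_nm"]],
            atol=1e-12)

    def test_half_offset_gives_mean_correction(self, rng):
        tru = _table(rng.uniform(0, 5000, size=(40, 3)))
        xyz = tru[["x_nm", "y_nm", "z_nm"]].to_numpy().copy()
        xyz[:20, 0] += 60.0   # offset x for half the points only
        det = _table(xyz)
        corrected = translation_correct(det, match(det, tru))
        shift = det["x_nm"].to_numpy() - corrected["x_nm"].to_numpy()
        np.testing.assert_allclose(shift, 30.0)
        resid = corrected["x_nm"].to_numpy() - tru["x_nm"].to_numpy()
        assert set(np.round(resid).astype(int)) == {-30, 30}


class TestEligibilityFilters:
    def test_dimmest_quartile_dropped(self, rng):
        tru = _table(rng.uniform(500, 1000, size=(100, 3)))
        tru["intensity_factor"] = rng.permutation(np.linspace(1, 2, 100))
        out = eligibility_filters(tru, border_nm=0.0, dimmest_fraction=0.25)
        assert len(out) == 75
        assert out["intensity_factor"].min() > np.quantile(
            tru["intensity_factor"], 0.249)

    def test_zero_border_drops_nothing(self, rng):
        tru = _table(rng.uniform(0, 1000, size=(50, 3)))
        tru["intensity_factor"] = 1.0
        out = eligibility_filters(tru, border_nm=0.0, dimmest_fraction=0.0)
        assert len(out) == 50

    def test_filters_commute(self, rng):
        """The combined call equals the intersection of the two single
        filters, whichever is taken first."""
        tru = _table(rng.uniform(0, 10000, size=(200, 3)))
        tru["intensity_factor"] = rng.uniform(1, 2, 200)
        extent = (10000.0, 10000.0)
        combined = eligibility_filters(tru, border_nm=1000.0,
                                       dimmest_fraction=0.25, extent_nm=extent)
        border_only = eligibility_filters(tru, border_nm=1000.0,
                                          dimmest_fraction=0.0, extent_nm=extent)
        dim_only = eligibility_filters(tru, border_nm=0.0, dimmest_fraction=0.25)
        key = lambda df: set(map(tuple, df[["x_nm", "y_nm"]].to_numpy()))
        assert key(combined) == key(border_only) & key(dim_only)
        assert key(combined) == key(dim_only) & key(border_only)

    def test_invalid_fraction_rejected(self, rng):
        tru = _table(rng.uniform(0, 100, size=(5, 3)))
        with pytest.raises(ValueError):
            eligibility_filters(tru, dimmest_fraction=1.0)
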