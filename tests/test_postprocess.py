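"""Drift correction, blinking grouping and Fourier shell correlation."""

import numpy as np
import pandas as pd
import pytest

from dhpsf.postprocess import (
    apply_drift,
    blockwise_fsc,
    estimate_drift_xcorr,
    fiducial_drift,
    fsc_resolution,
    group_blinking,
)


def _locs(x, y, z=None, frame=0, intensity=100.0):
    df = pd.DataFrame({
        "frame": frame,
        "x_nm": np.asarray(x, dtype=float),
        "y_nm": np.asarray(y, dtype=float),
        "intensity": intensity,
    })
    df["z_nm"] = 0.0 if z is None else np.asarray(z, dtype=float)
    df["kept"] = True
    return df


@pytest.fixture()
def clustered_scene(rng):
    """A structured point set re-observed in two temporal blocks, the
    second translated by (+100, -50) nm."""
    base_x = rng.uniform(0, 4000, 1500)
    base_y = rng.uniform(0, 4000, 1500)
    first = _locs(base_x, base_y, frame=rng.integers(0, 100, 1500))
    second = _locs(base_x + 100.0, base_y - 50.0,
                   frame=rng.integers(100, 200, 1500))
    return pd.concat([first, second], ignore_index=True)


class TestDriftXcorr:
    def test_two_block_translation_recovered(self, clustered_scene):
        bin_nm = 20.0
        trace = estimate_drift_xcorr(clustered_scene, block_frames=100,
                                     bin_nm=bin_nm)
        assert len(trace.blocks) == 2
        b0, b1 = trace.blocks.iloc[0], trace.blocks.iloc[1]
        assert (b0["shift_x_nm"], b0["shift_y_nm"]) == (0.0, 0.0)
        assert abs(b1["shift_x_nm"] - 100.0) <= 0.25 * bin_nm
        assert abs(b1["shift_y_nm"] + 50.0) <= 0.25 * bin_nm

    def test_single_block_identity(self, rng):
        locs = _locs(rng.uniform(0, 1000, 200), rng.uniform(0, 1000, 200),
                     frame=rng.integers(0, 50, 200))
        trace = estimate_drift_xcorr(locs, block_frames=100, bin_nm=20.0)
        assert len(trace.blocks) == 1
        assert trace.blocks[["shift_x_nm", "shift_y_nm"]].to_numpy().sum() == 0

    def test_apply_then_undo_is_identity(self, clustered_scene):
        trace = estimate_drift_xcorr(clustered_scene, block_frames=100,
                                     bin_nm=20.0)
        corrected = apply_drift(clustered_scene, trace, subtract=True)
        restored = apply_drift(corrected, trace, subtract=False)
        np.testing.assert_allclose(
            restored[["x_nm", "y_nm"]], clustered_scene[["x_nm", "y_nm"]])


class TestFiducialDrift:
    def test_constant_track_is_identity(self, rng):
        locs = _locs(rng.uniform(0, 500, 30), rng.uniform(0, 500, 30),
                     frame=np.arange(30))
        track = pd.DataFrame({"frame": np.arange(30), "x_nm": 70.0, "y_nm": 5.0})
        out = fiducial_drift(locs, track)
        np.testing.assert_allclose(out[["x_nm", "y_nm"]], locs[["x_nm", "y_nm"]])

    def test_linear_ramp_closed_form(self):
        frames = np.arange(11)
        locs = _locs(np.zeros(11), np.zeros(11), frame=frames)
        track = pd.DataFrame({"frame": frames, "x_nm": frames * 1.0, "y_nm": 0.0})
        out = fiducial_drift(locs, track)
        expected = -(frames - frames.mean())
        np.testing.assert_allclose(out["x_nm"], expected)

    def test_track_gaps_interpolated(self):
        locs = _locs([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], frame=[0, 5, 10])
        track = pd.DataFrame({"frame": [0, 10], "x_nm": [0.0, 10.0], "y_nm": 0.0})
        out = fiducial_drift(locs, track)
        np.testing.assert_allclose(out["x_nm"], [5.0, 0.0, -5.0])

    def test_no_overlap_rejected(self):
        locs = _locs([0.0], [0.0], frame=[100])
        track = pd.DataFrame({"frame": [0, 1], "x_nm": 0.0, "y_nm": 0.0})
        with pytest.raises(ValueError, match="overlap"):
            fiducial_drift(locs, track)


class TestGroupBlinking:
    def test_consecutive_frames_merge(self):
        locs = _locs([100.0, 100.0], [200.0, 200.0], z=[5.0, 5.0], frame=[3, 4])
        out = group_blinking(locs, dxy_max_nm=150.0, max_gap_frames=50)
        assert len(out) == 1
        assert out.loc[0, "multiplicity"] == 2
        assert out.loc[0, "x_nm"] == 100.0
        assert out.loc[0, "frame"] == 3

    def test_gap_beyond_limit_keeps_separate(self):
        locs = _locs([100.0, 100.0], [200.0, 200.0], frame=[0, 60])
        out = group_blinking(locs, dxy_max_nm=150.0, max_gap_frames=50)
        assert len(out) == 2

    def test_transitive_chain_groups_as_one(self):
        # A-B and B-C within reach, A-C not: transitivity links all three
        locs = _locs([0.0, 100.0, 200.0], [0.0, 0.0, 0.0], frame=[0, 1, 2])
        out = group_blinking(locs, dxy_max_nm=150.0, max_gap_frames=50)
        assert len(out) == 1
        assert out.loc[0, "multiplicity"] == 3
        assert out.loc[0, "x_nm"] == pytest.approx(100.0)

    def test_matches_networkx_components(self, rng):
        import networkx as nx

        n = 120
        locs = _locs(rng.uniform(0, 2000, n), rng.uniform(0, 2000, n),
                     z=rng.uniform(-500, 500, n), frame=rng.integers(0, 40, n))
        dxy, gap = 180.0, 10
        out = group_blinking(locs, dxy_max_nm=dxy, max_gap_frames=gap)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(locs["x_nm"][i] - locs["x_nm"][j],
                             locs["y_nm"][i] - locs["y_nm"][j])
                if d < dxy and abs(int(locs["frame"][i]) - int(locs["frame"][j])) <= gap:
                    g.add_edge(i, j)
        assert len(out) == nx.number_connected_components(g)

    def test_total_intensity_conserved(self, rng):
        n = 60
        locs = _locs(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
                     frame=rng.integers(0, 20, n),
                     intensity=rng.uniform(10, 100, n))
        out = group_blinking(locs, dxy_max_nm=200.0, max_gap_frames=10)
        assert out["intensity"].sum() == pytest.approx(locs["intensity"].sum())
        assert out["multiplicity"].sum() == n


class TestFsc:
    def test_self_correlation_is_unity(self, rng):
        locs = _locs(rng.uniform(0, 800, 400), rng.uniform(0, 800, 400),
                     z=rng.uniform(0, 800, 400))
        result = fsc_resolution(locs, voxel_nm=10.0, split=False)
        np.testing.assert_allclose(result.correlation, 1.0, atol=1e-9)
        assert result.resolution_nm == 2.0 * 10.0

    def test_zero_frequency_correlation_is_one(self, rng):
        locs = _locs(rng.uniform(0, 800, 2000), rng.uniform(0, 800, 2000),
                     z=rng.uniform(0, 800, 2000))
        result = fsc_resolution(locs, voxel_nm=10.0, seed=1)
        assert result.correlation[0] == pytest.approx(1.0, abs=1e-6)

    def test_structure_beats_uniform_noise(self, rng):
        n = 4000
        # spherical shell with 30 nm jitter vs uniform points, equal counts
        phi = rng.uniform(0, 2 * np.pi, n)
        cos_t = rng.uniform(-1, 1, n)
        sin_t = np.sqrt(1 - cos_t ** 2)
        r = 300.0
        sx = r * sin_t * np.cos(phi) + rng.normal(0, 30, n) + 400
        sy = r * sin_t * np.sin(phi) + rng.normal(0, 30, n) + 400
        sz = r * cos_t + rng.normal(0, 30, n) + 400
        shell = _locs(sx, sy, z=sz)
        uniform = _locs(rng.uniform(0, 800, n), rng.uniform(0, 800, n),
                        z=rng.uniform(0, 800, n))
        res_shell = fsc_resolution(shell, voxel_nm=5.0, seed=2)
        res_uniform = fsc_resolution(uniform, voxel_nm=5.0, seed=2)
        assert 50.0 <= res_shell.resolution_nm <= 200.0
        assert res_shell.resolution_nm < res_uniform.resolution_nm

    def test_resolution_stable_across_seeds(self, rng):
        n = 4000
        phi = rng.uniform(0, 2 * np.pi, n)
        cos_t = rng.uniform(-1, 1, n)
        sin_t = np.sqrt(1 - cos_t ** 2)
        sx = 300 * sin_t * np.cos(phi) + rng.normal(0, 30, n) + 400
        sy = 300 * sin_t * np.sin(phi) + rng.normal(0, 30, n) + 400
        sz = 300 * cos_t + rng.normal(0, 30, n) + 400
        shell = _locs(sx, sy, z=sz)
        res = [fsc_resolution(shell, voxel_nm=5.0, seed=s).resolution_nm
               for s in (1, 2, 3)]
        assert (max(res) - min(res)) / np.mean(res) <= 0.30

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fsc_resolution(_locs([0.0], [0.0]))


class TestBlockwiseFsc:
    def test_single_dense_block(self, rng):
        locs = _locs(rng.uniform(0, 900, 3000), rng.uniform(0, 900, 3000),
                     z=rng.uniform(0, 900, 3000))
        result = blockwise_fsc(locs, block_nm=1000.0, min_locs=1000,
                               voxel_nm=10.0, seed=4)
        assert len(result.per_block) == 1
        assert np.isfinite(result.mean_resolution_nm)

    def test_min_locs_above_total_empty(self, rng):
        locs = _locs(rng.uniform(0, 900, 100), rng.uniform(0, 900, 100),
                     z=rng.uniform(0, 900, 100))
        result = blockwise_fsc(locs, block_nm=1000.0, min_locs=1000,
                               voxel_nm=10.0)
        assert len(result.per_block) == 0
        assert np.isnan(result.mean_resolution_nm)
        assert sum(result.occupancy.values()) == 100

    def test_identical_blocks_equal_resolution(self, rng):
        n = 2500
        x = rng.uniform(50, 950, n)
        y = rng.uniform(50, 950, n)
        z = rng.uniform(50, 950, n)
        block_a = _locs(x, y, z=z)
        block_b = _locs(x + 2000.0, y, z=z)   # same structure, next block
        locs = pd.concat([block_a, block_b], ignore_index=True)
        result = blockwise_fsc(locs, block_nm=1000.0, min_locs=1000,
                               voxel_nm=10.0, seed=6)
        assert len(result.per_block) == 2
        r = [v.resolution_nm for v in result.per_block.values()]
        assert abs(r[0] - r[1]) / np.mean(r) <= 0.30
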