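"""Geometry: voxel indexing round trips and the pinhole projection primitive."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slnf.geometry import (
    CollimatorSpec,
    DetectorSpec,
    GeometryError,
    PinholeSpec,
    VolumeGrid,
    default_pinhole_pattern,
    geometry_hash,
    load_geometry,
    nearest_voxel,
    save_geometry,
    trace_ray,
    voxel_center,
)
from slnf.fixtures import profile_geometry
from slnf import reference

DET = DetectorSpec(n_rows=64, n_cols=128, pixel_pitch=0.6, raw_shape=(128, 256))


class TestVoxelIndexing:
    def test_single_voxel_grid_center(self):
        grid = VolumeGrid(n_x=1, n_y=1, n_z=1, spacing=2.0)
        assert voxel_center(grid, 0) == (0.0, 0.0, 2.0)

    def test_matches_nested_loop_enumeration(self):
        grid = VolumeGrid(n_x=3, n_y=3, n_z=3, spacing=2.0)
        expected = reference.enumerate_voxel_centers(3, 3, 3, 2.0)
        for i in range(grid.n_voxels):
            assert voxel_center(grid, i) == pytest.approx(expected[i])

    def test_default_grid_voxel_count(self):
        # the working volume is sampled at 60 x 100 x 200 points (2 mm pitch)
        grid = VolumeGrid()
        assert grid.n_voxels == 1_200_000
        assert (grid.n_x, grid.n_y, grid.n_z) == (60, 100, 200)

    def test_out_of_range_index_raises(self):
        grid = VolumeGrid(n_x=2, n_y=2, n_z=2)
        with pytest.raises(IndexError):
            voxel_center(grid, 8)
        with pytest.raises(IndexError):
            voxel_center(grid, -1)

    @settings(deadline=None)
    @given(st.integers(0, 12 * 20 * 20 - 1))
    def test_round_trip_all_voxels(self, index):
        grid = VolumeGrid(n_x=12, n_y=20, n_z=20, spacing=4.0)
        x, y, z = voxel_center(grid, index)
        idx, snap = nearest_voxel(grid, x, y, z)
        assert idx == index
        assert snap == 0.0

    def test_off_grid_snap_distance(self):
        grid = VolumeGrid(n_x=5, n_y=5, n_z=5, spacing=4.0)
        x, y, z = voxel_center(grid, 31)
        idx, snap = nearest_voxel(grid, x + 1.0, y, z)
        assert idx == 31
        assert snap == pytest.approx(1.0)

    def test_all_centers_matches_voxel_center(self):
        grid = VolumeGrid(n_x=4, n_y=3, n_z=5, spacing=1.5)
        centers = grid.all_centers()
        for i in (0, 7, 29, grid.n_voxels - 1):
            assert centers[i] == pytest.approx(voxel_center(grid, i))


class TestTraceRay:
    def test_on_axis_ray_hits_center_pixel(self):
        ph = PinholeSpec(center=(0.0, 0.0))
        pix = trace_ray((0.0, 0.0, 100.0), ph, DET)
        row, col = divmod(pix, DET.n_cols)
        assert row == DET.n_rows // 2
        assert col == DET.n_cols // 2

    def test_similar_triangles_offset(self):
        # source on-axis, pinhole at x=10, offset 30, z=100:
        # the hit sits at x = 10 + 10 * 30/100 = 13 mm
        ph = PinholeSpec(center=(10.0, 0.0))
        pix = trace_ray((0.0, 0.0, 100.0), ph, DET)
        col = pix % DET.n_cols
        assert col == int(np.floor((13.0 + DET.width / 2) / DET.pixel_pitch))

    def test_ray_outside_fov_returns_none(self):
        ph = PinholeSpec(center=(0.0, 0.0), fov_half_angle=45.0)
        assert trace_ray((300.0, 0.0, 10.0), ph, DET) is None

    def test_source_on_plate_plane_degenerate(self):
        ph = PinholeSpec(center=(0.0, 0.0))
        with pytest.raises(GeometryError):
            trace_ray((5.0, 5.0, 0.0), ph, DET)

    def test_magnification_sign_is_inverted(self):
        # a source moving +x moves the hit -x relative to the pinhole axis
        ph = PinholeSpec(center=(0.0, 0.0))
        col0 = trace_ray((0.0, 0.0, 100.0), ph, DET) % DET.n_cols
        col_plus = trace_ray((20.0, 0.0, 100.0), ph, DET) % DET.n_cols
        assert col_plus < col0

    @settings(deadline=None, max_examples=200)
    @given(
        sx=st.floats(-30, 30), sy=st.floats(-12, 12),
        sz=st.floats(40, 300),
        px=st.floats(-20, 20), py=st.floats(-10, 10),
    )
    def test_matches_independent_projection_oracle(self, sx, sy, sz, px, py):
        ph = PinholeSpec(center=(px, py))
        got = trace_ray((sx, sy, sz), ph, DET)
        want = reference.project_point(
            (sx, sy, sz), (px, py), DET.plane_offset, DET.pixel_pitch,
            DET.n_rows, DET.n_cols, ph.fov_half_angle,
        )
        if want is None:
            assert got is None
        else:
            assert got == want[0] * DET.n_cols + want[1]

    def test_scale_consistency_of_lateral_offset(self, rng):
        # doubling the source's lateral offset doubles the image point's
        # offset from the pinhole axis (continuous coordinates)
        for _ in range(200):
            z = rng.uniform(50, 300)
            off = rng.uniform(1, 10)
            ph = (0.0, 0.0)
            m = DET.plane_offset / z
            hit1 = -off * m
            hit2 = -2 * off * m
            assert hit2 == pytest.approx(2 * hit1)


class TestSpecsValidation:
    def test_detector_bin_consistency_enforced(self):
        with pytest.raises(GeometryError):
            DetectorSpec(n_rows=10, n_cols=10, raw_shape=(21, 20), bin_factor=2)

    def test_pinhole_must_fit_plate(self):
        with pytest.raises(GeometryError):
            CollimatorSpec(
                pinholes=(PinholeSpec(center=(100.0, 0.0)),),
                plate_extent=(80.0, 40.0),
            )

    def test_default_detector_matches_acquisition_format(self):
        det = DetectorSpec()
        assert (det.n_rows, det.n_cols) == (257, 515)
        assert det.raw_shape == (514, 1030)
        assert det.n_pixels == 132_355

    def test_default_pattern_deterministic_and_on_plate(self):
        a = default_pinhole_pattern()
        b = default_pinhole_pattern()
        assert a == b
        assert len(a) == 9
        for ph in a:
            assert abs(ph.center[0]) <= 40 and abs(ph.center[1]) <= 20


class TestConfigIO:
    def test_yaml_round_trip_preserves_hash(self, tmp_path, tiny_model):
        path = tmp_path / "geom.yaml"
        save_geometry(tiny_model, path)
        loaded = load_geometry(path)
        assert geometry_hash(loaded) == geometry_hash(tiny_model)
        assert loaded.grid == tiny_model.grid
        assert loaded.detector == tiny_model.detector

    def test_missing_key_is_config_error(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("detector: {rows: 10}\n")
        with pytest.raises(GeometryError):
            load_geometry(p)

    def test_profiles_differ_in_hash(self):
        hashes = {geometry_hash(profile_geometry(p)) for p in ("tiny", "default", "full_scale")}
        assert len(hashes) == 3
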