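"""Simulator: Poisson statistics, phantom layout, binning, backgrounds."""

import numpy as np
import pytest

from slnf.simulator import (
    AcquisitionConfig,
    HotBackground,
    SourceSpec,
    bin_image,
    expected_image,
    generate_grid_phantom,
    simulate_acquisition,
)


def _mid_source(model, A):
    """A well-covered source at the center of the grid's far half."""
    grid = model.grid
    z = (grid.n_z * 3 // 4) * grid.spacing
    return SourceSpec(position=(0.0, 0.0, z), activity=15.0)


class TestExpectedImage:
    def test_zero_activity_zero_rate(self, tiny_model, tiny_matrix):
        src = SourceSpec(position=(0.0, 0.0, 40.0), activity=0.0)
        cfg = AcquisitionConfig(seed=1)
        lam, _ = expected_image([src], tiny_matrix, tiny_model.grid, cfg)
        assert not lam.any()
        stack, _ = simulate_acquisition([src], tiny_matrix, tiny_model.grid, cfg)
        assert not stack.any()

    def test_source_outside_grid_rejected(self, tiny_model, tiny_matrix):
        cfg = AcquisitionConfig()
        with pytest.raises(ValueError, match="outside"):
            expected_image(
                [SourceSpec(position=(500.0, 0.0, 40.0))],
                tiny_matrix, tiny_model.grid, cfg,
            )

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            SourceSpec(position=(0, 0, 40), activity=-1.0)

    def test_penetration_mass_fraction(self, tiny_model, tiny_matrix):
        src = _mid_source(tiny_model, tiny_matrix)
        on = AcquisitionConfig(penetration_fraction=0.075)
        off = AcquisitionConfig(penetration_fraction=0.0)
        lam_on, _ = expected_image([src], tiny_matrix, tiny_model.grid, on)
        lam_off, _ = expected_image([src], tiny_matrix, tiny_model.grid, off)
        assert lam_on.sum() == pytest.approx(1.075 * lam_off.sum())
        # the smear is uniform: every pixel gained the same amount
        gain = lam_on - lam_off
        assert np.ptp(gain) == pytest.approx(0.0)

    def test_hot_background_adds_counts_everywhere_visible(self, tiny_model, tiny_matrix):
        src = _mid_source(tiny_model, tiny_matrix)
        hot = HotBackground(lo=(-20, -30, 30), hi=(20, 30, 70), activity_mbq=120.0)
        cfg = AcquisitionConfig(hot_background=hot, penetration_fraction=0.0)
        lam_hot, _ = expected_image([src], tiny_matrix, tiny_model.grid, cfg)
        lam_plain, _ = expected_image(
            [src], tiny_matrix, tiny_model.grid,
            AcquisitionConfig(penetration_fraction=0.0),
        )
        assert lam_hot.sum() > lam_plain.sum()
        assert (lam_hot >= lam_plain - 1e-12).all()

    def test_snap_metadata_records_quantization(self, tiny_model, tiny_matrix):
        grid = tiny_model.grid
        src = SourceSpec(position=(1.0, 2.0, 41.0))  # off-grid on purpose
        _, meta = expected_image([src], tiny_matrix, grid, AcquisitionConfig())
        assert meta["snap_distances_mm"][0] > 0
        assert meta["requested_positions_mm"][0] == [1.0, 2.0, 41.0]


class TestPoissonSampling:
    def test_sample_mean_matches_rate(self, tiny_model, tiny_matrix):
        src = _mid_source(tiny_model, tiny_matrix)
        cfg = AcquisitionConfig(n_repeats=1000, penetration_fraction=0.0, seed=99)
        lam, _ = expected_image([src], tiny_matrix, tiny_model.grid, cfg)
        stack, _ = simulate_acquisition([src], tiny_matrix, tiny_model.grid, cfg)
        hot = np.nonzero(lam)[0]
        mean = stack[:, hot].mean(axis=0)
        tol = 5 * np.sqrt(lam[hot]) / np.sqrt(cfg.n_repeats)
        assert (np.abs(mean - lam[hot]) <= tol).all()

    def test_seed_determinism(self, tiny_model, tiny_matrix):
        src = _mid_source(tiny_model, tiny_matrix)
        cfg = AcquisitionConfig(n_repeats=4, seed=7)
        s1, _ = simulate_acquisition([src], tiny_matrix, tiny_model.grid, cfg)
        s2, _ = simulate_acquisition([src], tiny_matrix, tiny_model.grid, cfg)
        assert np.array_equal(s1, s2)
        s3, _ = simulate_acquisition(
            [src], tiny_matrix, tiny_model.grid, AcquisitionConfig(n_repeats=4, seed=8)
        )
        assert not np.array_equal(s1, s3)

    def test_exposure_scaling_doubles_mean(self, tiny_model, tiny_matrix):
        src = _mid_source(tiny_model, tiny_matrix)
        base = AcquisitionConfig(exposure=8.0, n_repeats=300, seed=3,
                                 penetration_fraction=0.0)
        double = AcquisitionConfig(exposure=16.0, n_repeats=300, seed=4,
                                   penetration_fraction=0.0)
        s1, _ = simulate_acquisition([src], tiny_matrix, tiny_model.grid, base)
        s2, _ = simulate_acquisition([src], tiny_matrix, tiny_model.grid, double)
        m1, m2 = s1.sum(axis=1).mean(), s2.sum(axis=1).mean()
        assert m2 == pytest.approx(2 * m1, rel=0.05)

    def test_default_protocol_shape(self):
        # the acquisition protocol: 10 measurements of 8 s each
        cfg = AcquisitionConfig()
        assert cfg.n_repeats == 10
        assert cfg.exposure == 8.0


class TestPhantom:
    def test_pairwise_distances(self):
        ph = generate_grid_phantom(spacing=20.0)
        pos = np.array([s.position for s in ph])

        def d(a, b):
            return np.linalg.norm(pos[a - 1] - pos[b - 1])

        assert d(1, 2) == pytest.approx(20.0)   # adjacent, same row
        assert d(1, 3) == pytest.approx(40.0)   # row ends
        assert d(7, 9) == pytest.approx(40.0)
        assert d(3, 5) == pytest.approx(28.28, abs=0.01)  # diagonal neighbors
        assert d(1, 4) == pytest.approx(20.0)   # adjacent rows

    def test_layout_in_yz_plane(self):
        ph = generate_grid_phantom(spacing=20.0, origin_offset=(0.0, 0.0, 120.0))
        pos = np.array([s.position for s in ph])
        assert (pos[:, 0] == 0).all()
        assert sorted(set(pos[:, 1])) == [-20.0, 0.0, 20.0]
        assert sorted(set(pos[:, 2])) == [120.0, 140.0, 160.0]

    def test_positions_inside_default_grid(self, default_model):
        xs, ys, zs = default_model.grid.axes()
        for s in generate_grid_phantom(origin_offset=(0.0, 0.0, 120.0)):
            x, y, z = s.position
            assert xs[0] <= x <= xs[-1]
            assert ys[0] <= y <= ys[-1]
            assert zs[0] <= z <= zs[-1]

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            generate_grid_phantom(spacing=0.0)


class TestBinning:
    def test_uniform_input(self):
        assert (bin_image(np.ones((8, 10))) == 4).all()

    def test_count_conservation_random(self, rng):
        raw = rng.poisson(3.0, size=(514, 1030))
        binned = bin_image(raw)
        assert binned.shape == (257, 515)
        assert binned.sum() == raw.sum()

    def test_block_sums(self, rng):
        raw = rng.integers(0, 10, size=(4, 6))
        binned = bin_image(raw)
        assert binned[0, 0] == raw[:2, :2].sum()
        assert binned[1, 2] == raw[2:4, 4:6].sum()

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            bin_image(np.ones((7, 10)))
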