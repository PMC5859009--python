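"""Ground-truth placement, bit corruption, and image rendering."""

import numpy as np
import pytest

from xmerfish.simulate import (
    FieldGeometry,
    OpticsModel,
    corrupt_bits,
    place_molecules,
    render_stack,
    simulate_cell_field,
    simulate_smfish,
)


class TestPlacement:
    def test_poisson_molecule_count(self, assigned_codebook):
        """Expected count = density × FOV area (pre-expansion)."""
        geom = FieldGeometry(fov_x=100, fov_y=100)
        counts = [
            len(place_molecules(assigned_codebook, 1.0, geom, seed=s))
            for s in range(5)
        ]
        mean = np.mean(counts)
        # Poisson(10,000): mean ± 5 sd/sqrt(5)
        assert abs(mean - 10_000) < 5 * 100 / np.sqrt(5)

    def test_determinism(self, assigned_codebook, small_geometry):
        a = place_molecules(assigned_codebook, 0.5, small_geometry, seed=11)
        b = place_molecules(assigned_codebook, 0.5, small_geometry, seed=11)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.barcode_idx, b.barcode_idx)

    def test_expansion_scales_coordinates(self, assigned_codebook):
        """Same seed: expanded coordinates are exactly factor × unexpanded,
        so pairwise distances (and the areal density) scale with the factor."""
        g1 = FieldGeometry(fov_x=20, fov_y=20, expansion_factor=1.0)
        g2 = FieldGeometry(fov_x=20, fov_y=20, expansion_factor=2.3)
        t1 = place_molecules(assigned_codebook, 1.0, g1, seed=5)
        t2 = place_molecules(assigned_codebook, 1.0, g2, seed=5)
        assert np.allclose(t2.x, t1.x * 2.3)
        assert np.allclose(t2.y, t1.y * 2.3)
        d1 = np.hypot(t1.x[:, None] - t1.x, t1.y[:, None] - t1.y)
        d2 = np.hypot(t2.x[:, None] - t2.x, t2.y[:, None] - t2.y)
        iu = np.triu_indices(len(t1), 1)
        assert np.allclose(d2[iu], 2.3 * d1[iu])

    def test_blanks_receive_no_molecules(self, assigned_codebook, small_geometry):
        truth = place_molecules(assigned_codebook, 3.0, small_geometry, seed=2)
        assert not any(s.startswith("Blank-") for s in truth.species)

    def test_empty_codebook_rejected(self, small_geometry):
        from xmerfish.codebook import Codebook

        with pytest.raises(ValueError, match="empty"):
            place_molecules(Codebook(barcodes=[]), 1.0, small_geometry, seed=0)


class TestCorruption:
    def test_zero_rates_preserve_bits(self, assigned_codebook, small_geometry):
        truth = place_molecules(assigned_codebook, 1.0, small_geometry, seed=3)
        out = corrupt_bits(truth, 0.0, 0.0, seed=4)
        assert np.array_equal(out.bits_realized, out.bits_true)

    def test_full_drop_zeroes_all(self, assigned_codebook, small_geometry):
        truth = place_molecules(assigned_codebook, 1.0, small_geometry, seed=3)
        out = corrupt_bits(truth, 1.0, 0.0, seed=4)
        assert out.bits_realized.sum() == 0
        assert out.bits_true.sum() == 4 * len(out)

    def test_drop_fraction_matches_binomial(self, assigned_codebook):
        """P(≥1 of 4 on-bits dropped) = 1 − 0.9⁴ ≈ 0.3439 at p_drop = 0.1."""
        geom = FieldGeometry(fov_x=100, fov_y=100)
        truth = place_molecules(assigned_codebook, 1.0, geom, seed=6)
        out = corrupt_bits(truth, 0.1, 0.0, seed=7)
        dropped = (out.bits_true != out.bits_realized).any(axis=1)
        expect = 1 - 0.9**4
        sd = np.sqrt(expect * (1 - expect) / len(out))
        assert abs(dropped.mean() - expect) < 5 * sd

    def test_gain_only_adds_bits(self, assigned_codebook, small_geometry):
        truth = place_molecules(assigned_codebook, 1.0, small_geometry, seed=3)
        out = corrupt_bits(truth, 0.0, 0.5, seed=8)
        assert np.all(out.bits_realized >= out.bits_true)


class TestRendering:
    def test_empty_field_is_background(self, assigned_codebook, quiet_optics):
        geom = FieldGeometry(fov_x=5, fov_y=5)
        truth = place_molecules(assigned_codebook, 0.0, geom, seed=1, n_molecules=0)
        optics = OpticsModel(**{**quiet_optics.__dict__, "background": 7.0})
        stack = render_stack(truth, geom, optics, seed=2)
        assert np.allclose(stack.data, 7.0)

    def test_single_molecule_peak_and_off_bits(self, assigned_codebook, quiet_optics):
        geom = FieldGeometry(fov_x=5, fov_y=5)
        truth = place_molecules(assigned_codebook, 0.0, geom, seed=1, n_molecules=1)
        # put it exactly on a pixel center so the peak equals the amplitude
        truth.x[0], truth.y[0] = 20 * geom.pixel_um, 25 * geom.pixel_um
        stack = render_stack(truth, geom, quiet_optics, seed=2)
        on_bits = np.flatnonzero(truth.bits_realized[0])
        for bit in range(16):
            img = stack.bit_image(bit)[0]
            if bit in on_bits:
                assert img[25, 20] == pytest.approx(truth.amplitudes[0, bit], rel=1e-9)
            else:
                assert img.max() == 0.0

    def test_patch_sum_matches_discrete_gaussian(self, assigned_codebook, quiet_optics):
        """Flux in a 13×13 patch equals amplitude × Σ discretized Gaussian."""
        geom = FieldGeometry(fov_x=5, fov_y=5)
        truth = place_molecules(assigned_codebook, 0.0, geom, seed=1, n_molecules=1)
        truth.x[0], truth.y[0] = 22.3 * geom.pixel_um, 24.7 * geom.pixel_um
        stack = render_stack(truth, geom, quiet_optics, seed=2)
        bit = int(np.flatnonzero(truth.bits_realized[0])[0])
        img = stack.bit_image(bit)[0]
        patch = img[25 - 6:25 + 7, 22 - 6:22 + 7]
        yy, xx = np.mgrid[19:32, 16:29]
        s = quiet_optics.psf_sigma
        gauss = np.exp(-((xx - 22.3) ** 2 + (yy - 24.7) ** 2) / (2 * s**2))
        expected = truth.amplitudes[0, bit] * gauss.sum()
        assert patch.sum() == pytest.approx(expected, rel=0.01)

    def test_total_intensity_conservation(self, assigned_codebook, quiet_optics):
        """Noise-free stack flux = Σ amplitudes × discrete-PSF sums (+ background)."""
        geom = FieldGeometry(fov_x=10, fov_y=10)
        truth = place_molecules(assigned_codebook, 0.2, geom, seed=9)
        # keep molecules away from edges so no flux is clipped
        truth.x[:] = np.clip(truth.x, 2.0, 8.0)
        truth.y[:] = np.clip(truth.y, 2.0, 8.0)
        stack = render_stack(truth, geom, quiet_optics, seed=3)
        s = quiet_optics.psf_sigma
        r = int(np.ceil(6 * s))
        ax = np.arange(-r, r + 1)
        # discrete Gaussian sum depends on sub-pixel phase; compute per molecule
        total = 0.0
        for i in range(len(truth)):
            fx = truth.x[i] / geom.pixel_um
            fy = truth.y[i] / geom.pixel_um
            gx = np.exp(-((np.round(fx) + ax - fx) ** 2) / (2 * s**2)).sum()
            gy = np.exp(-((np.round(fy) + ax - fy) ** 2) / (2 * s**2)).sum()
            total += truth.amplitudes[i][truth.bits_realized[i] == 1].sum() * gx * gy
        assert stack.data.sum() == pytest.approx(total, rel=1e-6)

    def test_drift_length_validated(self, assigned_codebook, small_geometry, quiet_optics):
        truth = place_molecules(assigned_codebook, 0.1, small_geometry, seed=1)
        bad = OpticsModel(**{**quiet_optics.__dict__, "per_round_drift": ((1.0, 0.0),)})
        with pytest.raises(ValueError, match="drift"):
            render_stack(truth, small_geometry, bad, seed=0)

    def test_noise_free_rendering_deterministic(self, assigned_codebook, small_geometry, quiet_optics):
        truth = place_molecules(assigned_codebook, 0.2, small_geometry, seed=4)
        a = render_stack(truth, small_geometry, quiet_optics, seed=5)
        b = render_stack(truth, small_geometry, quiet_optics, seed=5)
        assert np.array_equal(a.data, b.data)


class TestSmfish:
    def test_single_bit_stack_shape(self, quiet_optics):
        geom = FieldGeometry(fov_x=10, fov_y=10)
        stack = simulate_smfish(np.array([[5.0, 5.0, 0.5]]), geom, quiet_optics, seed=0)
        assert stack.data.shape[:2] == (1, 1)
        assert stack.data[0, 0, 0].max() > 0


class TestCellField:
    def test_seed_mask_and_counts(self, assigned_codebook):
        geom = FieldGeometry(fov_x=40, fov_y=40)
        field = simulate_cell_field(assigned_codebook, 4, geom, seed=1,
                                    molecules_per_cell=200)
        assert field.seed_mask.max() == 4
        assert field.counts.shape == (4, 140)
        assert len(field.truth) == field.counts.sum()
        assert field.truth.cell_id.min() >= 1
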