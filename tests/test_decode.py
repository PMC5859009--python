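"""Registration, filtering, normalization, pixel decoding and assembly."""

import math

import numpy as np
import pytest

from xmerfish.codebook import generate_mhd4
from xmerfish.decode import (
    SINGLE_BIT_DROP_DISTANCE,
    SINGLE_BIT_GAIN_DISTANCE,
    DecodeConfig,
    NormalizedPixelField,
    assemble_molecules,
    decode_pixels,
    decode_stack,
    match_to_truth,
    normalize_bits,
    preprocess,
    register_rounds,
)
from xmerfish.simulate import (
    FieldGeometry,
    OpticsModel,
    place_molecules,
    render_stack,
)


def _render(codebook, geometry, optics, density=0.2, seed=1):
    truth = place_molecules(codebook, density, geometry, seed=seed)
    stack = render_stack(truth, geometry, optics, seed=seed + 1)
    return truth, stack


class TestRegistration:
    def test_zero_drift_recovers_zero(self, assigned_codebook, small_geometry):
        optics = OpticsModel(bead_count=15)
        _, stack = _render(assigned_codebook, small_geometry, optics)
        reg = register_rounds(stack)
        assert np.all(np.abs(reg.offsets) < 0.05)

    def test_injected_drift_recovered(self, assigned_codebook, small_geometry):
        """Drift of (3.2, −1.7) px in round 5 is recovered within 0.2 px."""
        drift = [(0.0, 0.0)] * 8
        drift[4] = (3.2, -1.7)
        optics = OpticsModel(bead_count=15, per_round_drift=tuple(drift))
        _, stack = _render(assigned_codebook, small_geometry, optics)
        reg = register_rounds(stack)
        assert reg.offsets[4] == pytest.approx([3.2, -1.7], abs=0.2)
        others = np.delete(reg.offsets, 4, axis=0)
        assert np.all(np.abs(others) < 0.2)
        assert reg.residual_px < 0.5

    def test_flat_beadless_images_fail(self, assigned_codebook):
        geom = FieldGeometry(fov_x=5, fov_y=5)
        optics = OpticsModel(bead_count=0, background=0, read_noise_sd=0,
                             shot_noise=False)
        truth = place_molecules(assigned_codebook, 0.0, geom, seed=0, n_molecules=0)
        stack = render_stack(truth, geom, optics, seed=1)
        with pytest.raises(RuntimeError, match="registration"):
            register_rounds(stack)


class TestPreprocess:
    def test_constant_image_vanishes(self):
        out = preprocess(np.full((64, 64), 37.0))
        assert np.all(np.abs(out) < 1e-6)

    def test_output_non_negative(self, rng):
        out = preprocess(rng.normal(100, 20, (64, 64)))
        assert out.min() >= 0

    def test_non_finite_rejected(self):
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            preprocess(img)

    def test_deconvolution_tightens_spot(self):
        """Fitted width after RL deconvolution < rendered width."""
        yy, xx = np.mgrid[0:41, 0:41]
        sigma = 1.6
        spot = 1000 * np.exp(-((xx - 20) ** 2 + (yy - 20) ** 2) / (2 * sigma**2))

        def width(img):
            w = np.clip(img, 0, None)
            tot = w.sum()
            cx = (xx * w).sum() / tot
            return np.sqrt(((xx - cx) ** 2 * w).sum() / tot)

        out = preprocess(spot, highpass_sigma=10, decon_iterations=10,
                         lowpass_sigma=0, psf_sigma=sigma)
        assert width(out) < width(spot)


class TestNormalization:
    def _field(self, codebook, geometry, seed=21):
        optics = OpticsModel(bead_count=0)
        truth = place_molecules(codebook, 0.5, geometry, seed=seed)
        stack = render_stack(truth, geometry, optics, seed=seed + 1)
        from xmerfish.decode import preprocess_stack

        filtered, _ = preprocess_stack(stack, DecodeConfig())
        return filtered

    def test_identical_bits_equal_scales(self, assigned_codebook):
        img = np.abs(np.random.default_rng(0).normal(10, 3, (1, 32, 32))) + 1
        filtered = np.repeat(img[None], 16, axis=0)
        out = normalize_bits(filtered, assigned_codebook)
        assert np.ptp(out.scale_factors) / out.scale_factors.mean() < 1e-6

    def test_scale_equivariance(self, assigned_codebook, small_geometry):
        """Doubling one bit's image doubles its scale factor (within 5%)."""
        filtered = self._field(assigned_codebook, small_geometry)
        out = normalize_bits(filtered, assigned_codebook)
        boosted = filtered.copy()
        boosted[6] *= 2.0
        out2 = normalize_bits(boosted, assigned_codebook)
        ratio = (out2.scale_factors[6] / out.scale_factors[6]) / (
            out2.scale_factors[0] / out.scale_factors[0]
        )
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_iteration_converges(self, assigned_codebook, small_geometry):
        filtered = self._field(assigned_codebook, small_geometry)
        out = normalize_bits(filtered, assigned_codebook)
        assert out.n_iterations <= 10

    def test_dead_bit_raises(self, assigned_codebook):
        filtered = np.ones((16, 1, 16, 16))
        filtered[4] = 0.0
        with pytest.raises(ValueError, match="bit 5"):
            normalize_bits(filtered, assigned_codebook)


class TestPixelDecoding:
    def test_single_bit_error_distances_closed_form(self):
        """√(2−√3) ≈ 0.5176 (dropped bit) and √(2−4/√5) ≈ 0.4595 (extra bit)."""
        assert SINGLE_BIT_DROP_DISTANCE == pytest.approx(math.sqrt(2 - math.sqrt(3)))
        assert SINGLE_BIT_DROP_DISTANCE == pytest.approx(0.5176, abs=1e-4)
        assert SINGLE_BIT_GAIN_DISTANCE == pytest.approx(math.sqrt(2 - 4 / math.sqrt(5)))
        assert SINGLE_BIT_GAIN_DISTANCE == pytest.approx(0.4595, abs=1e-4)

    def _field_from_vectors(self, vectors):
        v = np.asarray(vectors, dtype=float).T[:, None, None, :]  # (16,1,1,n)
        return NormalizedPixelField(
            vectors=v,
            scale_factors=np.ones(16),
            gate_mask=np.ones(v.shape[1:], dtype=bool),
        )

    def test_exact_barcode_assigned_at_zero(self, codebook):
        b = codebook.barcodes[17]
        field = self._field_from_vectors([np.array(b.bits, float)])
        amap, dmap = decode_pixels(field, codebook)
        assert amap[0, 0, 0] == 17
        assert dmap[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_dropped_bit_assigned_at_threshold(self, codebook):
        """A weight-3 pattern (one on-bit lost) decodes at the defining distance."""
        for idx in (0, 63, 139):
            bits = np.array(codebook.barcodes[idx].bits, float)
            on = np.flatnonzero(bits)
            v = bits.copy()
            v[on[1]] = 0.0
            amap, dmap = decode_pixels(self._field_from_vectors([v]), codebook)
            assert amap[0, 0, 0] == idx
            assert dmap[0, 0, 0] == pytest.approx(SINGLE_BIT_DROP_DISTANCE, abs=1e-9)

    def test_gained_bit_assigned_below_threshold(self, codebook):
        for idx in (5, 100):
            bits = np.array(codebook.barcodes[idx].bits, float)
            off = np.flatnonzero(bits == 0)
            v = bits.copy()
            v[off[0]] = 1.0
            amap, dmap = decode_pixels(self._field_from_vectors([v]), codebook)
            assert amap[0, 0, 0] == idx
            assert dmap[0, 0, 0] == pytest.approx(SINGLE_BIT_GAIN_DISTANCE, abs=1e-9)

    def test_zero_vector_unassigned(self, codebook):
        amap, _ = decode_pixels(self._field_from_vectors([np.zeros(16)]), codebook)
        assert amap[0, 0, 0] == -1


class TestAssembly:
    def _map(self, shape=(3, 20, 20)):
        return np.full(shape, -1, dtype=np.int64)

    def test_diagonal_pixels_merge(self, codebook, small_geometry):
        """26-connectivity joins (z,y,x) and (z+1,y+1,x+1)."""
        m = self._map()
        m[0, 5, 5] = 7
        m[1, 6, 6] = 7
        mols = assemble_molecules(m, codebook, small_geometry)
        assert len(mols) == 1
        assert mols[0].n_pixels == 2

    def test_different_barcodes_stay_separate(self, codebook, small_geometry):
        m = self._map()
        m[0, 5, 5] = 7
        m[0, 5, 6] = 8
        mols = assemble_molecules(m, codebook, small_geometry)
        assert len(mols) == 2

    def test_min_size_filters(self, codebook, small_geometry):
        m = self._map()
        m[0, 5, 5] = 7
        m[0, 10, 10] = 9
        m[0, 10, 11] = 9
        mols = assemble_molecules(m, codebook, small_geometry, min_size=2)
        assert [mol.barcode_id for mol in mols] == [9]

    def test_matches_flood_fill_oracle(self, codebook, small_geometry, rng):
        """Component counts agree with a brute-force flood fill on random maps."""

        def flood_count(label_map):
            seen = np.zeros(label_map.shape, dtype=bool)
            count = 0
            nz, ny, nx = label_map.shape
            for z0, y0, x0 in zip(*np.nonzero(label_map >= 0)):
                if seen[z0, y0, x0]:
                    continue
                count += 1
                val = label_map[z0, y0, x0]
                stack = [(z0, y0, x0)]
                seen[z0, y0, x0] = True
                while stack:
                    z, y, x = stack.pop()
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                zz, yy, xx = z + dz, y + dy, x + dx
                                if (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                                        and not seen[zz, yy, xx]
                                        and label_map[zz, yy, xx] == val):
                                    seen[zz, yy, xx] = True
                                    stack.append((zz, yy, xx))
            return count

        for trial in range(20):
            m = rng.choice([-1, -1, -1, 0, 1, 2], size=(3, 20, 20)).astype(np.int64)
            mols = assemble_molecules(m, codebook, small_geometry)
            assert len(mols) == flood_count(m)

    def test_centroid_weighted(self, codebook, small_geometry):
        m = self._map()
        m[0, 5, 5] = 3
        m[0, 5, 6] = 3
        w = np.zeros(m.shape)
        w[0, 5, 5] = 3.0
        w[0, 5, 6] = 1.0
        mols = assemble_molecules(m, codebook, small_geometry, intensity=w)
        assert mols[0].x_um == pytest.approx(5.25 * small_geometry.pixel_um)


class TestEndToEnd:
    def test_low_density_perfect_recovery(self, assigned_codebook, small_geometry):
        """Noise-free decoding at sparse density recovers every molecule."""
        optics = OpticsModel(bead_count=0)
        truth = place_molecules(assigned_codebook, 0.05, small_geometry, seed=42)
        stack = render_stack(truth, small_geometry, optics, seed=43)
        mols, report = decode_stack(stack, assigned_codebook, register=False)
        res = match_to_truth(mols, truth, radius_um=0.5, codebook=assigned_codebook)
        assert res.efficiency == pytest.approx(1.0, abs=0.05)
        assert res.precision == pytest.approx(1.0, abs=0.05)

    def test_empty_molecule_list_zero_efficiency(self, assigned_codebook, small_geometry):
        truth = place_molecules(assigned_codebook, 0.1, small_geometry, seed=1)
        res = match_to_truth([], truth, radius_um=0.5)
        assert res.efficiency == 0.0

    def test_shuffled_labels_near_chance(self, assigned_codebook, small_geometry):
        """Random barcode labels on true positions match at ~1/129 rate."""
        geom = FieldGeometry(fov_x=60, fov_y=60)
        truth = place_molecules(assigned_codebook, 1.0, geom, seed=2)
        rng = np.random.default_rng(3)
        from xmerfish.decode import DecodedMolecule

        gene_ids = [b.index for b in assigned_codebook
                    if b.label and not b.label.startswith("Blank-")]
        mols = [
            DecodedMolecule(
                barcode_id=int(rng.choice(gene_ids)),
                label="x",
                x_um=truth.x[i], y_um=truth.y[i], z_um=truth.z[i],
                n_pixels=1, distance=0.0, was_corrected=False,
            )
            for i in range(len(truth))
        ]
        res = match_to_truth(mols, truth, radius_um=0.5)
        assert res.efficiency < 5 / 129

    def test_invalid_radius(self, assigned_codebook, small_geometry):
        truth = place_molecules(assigned_codebook, 0.1, small_geometry, seed=1)
        with pytest.raises(ValueError, match="radius"):
            match_to_truth([], truth, radius_um=0.0)
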