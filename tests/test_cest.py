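"""CEST mapping: echo averaging, MTRasym band arithmetic, B0 estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gliohab as gh
from gliohab.cest import inverted_lorentzian

from conftest import make_zspec

OFFSETS = gh.default_offsets()


class TestEchoAveraging:
    def _sage(self, e1, e2, e3=None):
        echoes = [e1, e2] + ([e3] if e3 is not None else [])
        sig = np.stack([np.full((2, 2, 1, len(OFFSETS)), v) for v in echoes])
        s0 = np.stack([np.full((2, 2, 1), 100.0 * (i + 1))
                       for i in range(len(echoes))])
        return gh.ZSpectrumVolume(sig, OFFSETS, s0, np.ones((2, 2, 1), bool))

    def test_identical_echoes_pass_through(self):
        out = gh.average_sage_echoes(self._sage(5.0, 5.0))
        assert np.all(out.signal == 5.0)

    def test_arithmetic_mean_of_first_two(self):
        out = gh.average_sage_echoes(self._sage(2.0, 4.0))
        assert np.all(out.signal == 3.0)
        assert np.all(out.s0 == 150.0)

    def test_third_echo_ignored(self):
        with_three = gh.average_sage_echoes(self._sage(2.0, 4.0, 99.0))
        with_two = gh.average_sage_echoes(self._sage(2.0, 4.0))
        np.testing.assert_array_equal(with_three.signal, with_two.signal)

    def test_single_echo_rejected(self):
        sig = np.full((2, 2, 1, len(OFFSETS)), 1.0)
        vol = gh.ZSpectrumVolume(sig, OFFSETS, np.ones((2, 2, 1)),
                                 np.ones((2, 2, 1), bool))
        with pytest.raises(ValueError, match="echo"):
            gh.average_sage_echoes(vol)


class TestMTRAsymPointwise:
    def test_flat_spectrum_is_zero(self):
        assert gh.mtr_asym_at_3ppm(OFFSETS, 0.8 * np.ones_like(OFFSETS), 1.0) == 0.0

    def test_band_average_closed_form(self):
        ratio = np.ones_like(OFFSETS)
        ratio[np.abs(OFFSETS + 3.0) <= 0.2 + 1e-9] = 0.90
        ratio[np.abs(OFFSETS - 3.0) <= 0.2 + 1e-9] = 0.80
        assert gh.mtr_asym_at_3ppm(OFFSETS, ratio, 1.0) == pytest.approx(0.10)

    def test_mirroring_negates(self, rng):
        ratio = rng.uniform(0.5, 1.0, size=len(OFFSETS))
        fwd = gh.mtr_asym_at_3ppm(OFFSETS, ratio, 1.0)
        # mirrored spectrum: S'(w) = S(-w); resort onto the increasing grid
        mirrored = ratio[np.argsort(-OFFSETS)]
        rev = gh.mtr_asym_at_3ppm(np.sort(-OFFSETS), mirrored, 1.0)
        assert rev == pytest.approx(-fwd, abs=1e-12)

    def test_missing_band_named(self):
        near_only = OFFSETS[np.abs(OFFSETS) < 1.0]
        with pytest.raises(ValueError, match="negative"):
            gh.mtr_asym_at_3ppm(near_only, np.ones_like(near_only), 1.0)


class TestMTRAsymMap:
    def test_uniform_phantom_constant_map(self):
        z, truth = gh.generate_cest_phantom(asym_amplitude=0.04, shape=(4, 4, 2))
        m = gh.compute_mtr_asym_map(z)
        np.testing.assert_allclose(m.values, truth.values, atol=1e-9)

    def test_empty_mask_yields_empty_map(self):
        ratio = np.ones((3, 3, 1, len(OFFSETS)))
        vol = make_zspec(ratio, mask=np.zeros((3, 3, 1), bool))
        m = gh.compute_mtr_asym_map(vol)
        assert not m.mask.any()
        assert np.all(np.isnan(m.values))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4),
           seed=st.integers(0, 2**16))
    def test_scale_invariance(self, scale, seed):
        """MTRasym is a ratio: scaling signal and S0 jointly changes nothing."""
        rng = np.random.default_rng(seed)
        ratio = rng.uniform(0.5, 1.0, size=(2, 2, 1, len(OFFSETS)))
        base = gh.compute_mtr_asym_map(make_zspec(ratio, s0_value=100.0))
        scaled = gh.compute_mtr_asym_map(make_zspec(ratio, s0_value=100.0 * scale))
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_antisymmetry_voxelwise(self, seed):
        """Reflecting the offset axis negates the map at every voxel."""
        rng = np.random.default_rng(seed)
        ratio = rng.uniform(0.5, 1.0, size=(3, 2, 1, len(OFFSETS)))
        fwd = gh.compute_mtr_asym_map(make_zspec(ratio))
        mirrored = ratio[..., ::-1]
        rev = gh.compute_mtr_asym_map(make_zspec(mirrored, offsets=np.sort(-OFFSETS)))
        np.testing.assert_allclose(rev.values, -fwd.values, atol=1e-12)


class TestB0Estimation:
    def test_symmetric_dip_centered_at_zero(self):
        ratio = inverted_lorentzian(OFFSETS, 0.8, 1.0, 0.0)
        vol = make_zspec(np.broadcast_to(ratio, (4, 4, 1, len(OFFSETS))).copy())
        b0 = gh.estimate_b0_shift(vol, n_clusters=4, seed=0)
        assert np.nanmax(np.abs(b0.delta_ppm)) < 1e-3

    def test_planted_uniform_shift_recovered(self):
        z, _ = gh.generate_cest_phantom(asym_amplitude=0.02,
                                        b0_field=np.full((6, 6, 2), 0.2), seed=3)
        b0 = gh.estimate_b0_shift(z, n_clusters=8, seed=0)
        assert np.nanmean(np.abs(b0.delta_ppm - 0.2)) < 0.05

    def test_two_blocks_recovered_separately(self):
        field = np.zeros((6, 6, 2))
        field[:3] = 0.1
        field[3:] = -0.1
        z, _ = gh.generate_cest_phantom(asym_amplitude=0.0, b0_field=field, seed=4)
        b0 = gh.estimate_b0_shift(z, n_clusters=4, seed=0)
        assert abs(np.nanmean(b0.delta_ppm[:3]) - 0.1) < 0.05
        assert abs(np.nanmean(b0.delta_ppm[3:]) + 0.1) < 0.05

    def test_too_few_near_water_offsets(self):
        sparse = np.array([-3.2, -3.0, -2.8, 0.0, 2.8, 3.0, 3.2])
        vol = make_zspec(np.ones((2, 2, 1, len(sparse))), offsets=sparse)
        with pytest.raises(ValueError, match="near-water"):
            gh.estimate_b0_shift(vol)

    def test_identical_spectra_collapse_to_one_cluster(self):
        ratio = inverted_lorentzian(OFFSETS, 0.8, 1.0, 0.05)
        vol = make_zspec(np.broadcast_to(ratio, (3, 3, 1, len(OFFSETS))).copy())
        b0 = gh.estimate_b0_shift(vol, n_clusters=16, seed=0)
        assert np.allclose(b0.delta_ppm, b0.delta_ppm.flat[0])


class TestB0Correction:
    def test_zero_shift_is_identity(self):
        z, _ = gh.generate_cest_phantom(asym_amplitude=0.03, shape=(3, 3, 1))
        b0 = gh.B0ShiftMap(np.zeros((3, 3, 1)), np.zeros((3, 3, 1)))
        out = gh.b0_correct_zspectrum(z, b0)
        np.testing.assert_array_equal(out.signal, z.signal)

    def test_grid_step_shift_equals_neighbor(self, rng):
        """A one-grid-step shift is exact under linear interpolation."""
        offsets = np.arange(-3.0, 3.0 + 1e-9, 0.1)
        ratio = rng.uniform(0.5, 1.0, size=(2, 2, 1, len(offsets)))
        vol = make_zspec(ratio, offsets=offsets)
        b0 = gh.B0ShiftMap(np.full((2, 2, 1), 0.1), np.zeros((2, 2, 1)))
        out = gh.b0_correct_zspectrum(vol, b0)
        np.testing.assert_allclose(out.signal[..., :-1], vol.signal[..., 1:],
                                   rtol=1e-9)
        assert np.all(np.isnan(out.signal[..., -1]))

    def test_excess_shift_masks_voxel_out(self):
        z, _ = gh.generate_cest_phantom(asym_amplitude=0.0, shape=(2, 2, 1))
        delta = np.zeros((2, 2, 1))
        delta[0, 0, 0] = 5.0
        out = gh.b0_correct_zspectrum(z, gh.B0ShiftMap(delta, np.zeros_like(delta)))
        assert not out.mask[0, 0, 0]
        assert out.mask[1, 1, 0]

    def test_roundtrip_restores_symmetric_phantom(self):
        """Planted shift field, estimate + correct: MTRasym returns to ~0."""
        field = np.linspace(-0.15, 0.15, 6 * 6 * 2).reshape(6, 6, 2)
        z, _ = gh.generate_cest_phantom(asym_amplitude=0.0, b0_field=field)
        b0 = gh.estimate_b0_shift(z, n_clusters=32, seed=0)
        corrected = gh.b0_correct_zspectrum(z, b0)
        m = gh.compute_mtr_asym_map(corrected)
        assert np.nanmax(np.abs(m.values[m.mask])) < 1e-3
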