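"""Wavenumber estimation, compounding, trimming, and pipeline properties."""

import numpy as np
import pytest

import kmdev as km
from kmdev.inversion import CompoundConfig, compound_frequency

from conftest import plane_wave_field


SPACING = (1.6, 1.6, 2.0)


def _coords(shape):
    return np.meshgrid(
        *[np.arange(n) * s / 1000.0 for n, s in zip(shape, SPACING)],
        indexing="ij",
    )


class TestPhaseGradient:
    def test_plane_wave_recovers_wavenumber(self):
        X, _, _ = _coords((48, 16, 8))
        u = np.exp(1j * 157.08 * X)
        k = km.phase_gradient_k(u, SPACING, mode="2d")
        interior = k[1:-1]
        assert np.abs(interior / 157.08 - 1).max() < 0.005

    def test_constant_field_zero_wavenumber(self):
        u = np.full((16, 16, 4), 3.0 + 4.0j)
        assert km.phase_gradient_k(u, SPACING, mode="3d").max() == 0.0

    def test_oblique_wave_vector_norm(self):
        X, Y, _ = _coords((48, 48, 4))
        kx, ky = 100.0, 80.0
        u = np.exp(1j * (kx * X + ky * Y))
        k = km.phase_gradient_k(u, SPACING, mode="2d")
        expected = np.hypot(kx, ky)
        assert np.abs(k[1:-1, 1:-1] / expected - 1).max() < 0.005

    def test_all_zero_field_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            km.phase_gradient_k(np.zeros((8, 8, 4), complex), SPACING)

    def test_low_amplitude_voxels_flagged(self):
        u = np.exp(1j * 100.0 * _coords((16, 16, 4))[0])
        u[3, 3, 1] = 1e-15
        k = km.phase_gradient_k(u, SPACING, mode="2d")
        assert np.isnan(k[3, 3, 1])


class TestAmplitudeGradient:
    def test_decaying_wave_recovers_attenuation(self):
        X, _, _ = _coords((48, 16, 8))
        u = np.exp(-30.0 * X) * np.exp(1j * 150.0 * X)
        k = km.amplitude_gradient_k(u, SPACING, mode="2d")
        assert np.abs(k[1:-1] / 30.0 - 1).max() < 0.01

    def test_constant_amplitude_zero(self):
        X, _, _ = _coords((16, 16, 4))
        u = np.exp(1j * 120.0 * X)
        assert km.amplitude_gradient_k(u, SPACING, mode="2d").max() < 1e-9

    def test_diagonal_decay(self):
        X, Y, _ = _coords((32, 32, 4))
        a = 20.0
        u = np.exp(-a * (X + Y)) * np.exp(1j * 200.0 * X)
        k = km.amplitude_gradient_k(u, SPACING, mode="2d")
        assert np.abs(k[1:-1, 1:-1] / (a * np.sqrt(2)) - 1).max() < 0.01


class TestCompounding:
    def _maps(self, grid, kp, kpp, w):
        shape = (1, 1, 1) + grid.shape
        return km.WavenumberMaps(
            grid=grid,
            k_prime=np.full(shape, kp),
            k_doubleprime=np.full(shape, kpp),
            weights=np.full(shape, w),
        )

    def test_single_contribution_division(self, small_grid):
        maps = self._maps(small_grid, 157.08, 30.0, 1.0)
        sws, pr = compound_frequency(maps, 30.0)
        assert sws[0, 0, 0] == pytest.approx(2 * np.pi * 30 / 157.08, rel=1e-12)
        assert pr[0, 0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_weighted_mean_of_contributions(self):
        g = km.AcquisitionGrid((4, 4, 4), SPACING, 8, (25.0,))
        shape = (2, 1, 1) + g.shape
        kp = np.stack([np.full((1, 1) + g.shape, 100.0), np.full((1, 1) + g.shape, 200.0)])
        w = np.stack([np.full((1, 1) + g.shape, 1.0), np.full((1, 1) + g.shape, 3.0)])
        maps = km.WavenumberMaps(
            grid=g, k_prime=kp, k_doubleprime=np.zeros(shape), weights=w
        )
        # the 4³ grid is below the minimum-wavelength rule; disable it to
        # test the weighted-mean arithmetic in isolation
        sws, _ = compound_frequency(maps, 25.0, CompoundConfig(min_cycles_per_fov=0.0))
        # weighted mean k' = (100·1 + 200·3)/4 = 175 → SWS = 2π·25/175
        assert sws[0, 0, 0] == pytest.approx(0.897598, abs=1e-6)

    def test_zero_weight_voxels_invalid(self, small_grid):
        maps = self._maps(small_grid, 157.08, 30.0, 0.0)
        sws, pr = compound_frequency(maps, 30.0)
        assert np.isnan(sws).all() and np.isnan(pr).all()

    def test_multifrequency_harmonic_mean(self, small_grid):
        shape = small_grid.shape
        sws_f = [np.full(shape, v) for v in (1.2, 1.25, 1.3, 1.35)]
        pr_f = [np.full(shape, 1.0)] * 4
        pm = km.compound_multifrequency(sws_f, pr_f, small_grid, "2d")
        assert pm.sws[0, 0, 0] == pytest.approx(1.272546, abs=1e-6)
        # two-value case and idempotence
        pm2 = km.compound_multifrequency(
            [np.full(shape, 1.0), np.full(shape, 2.0)],
            [np.full(shape, 1.0)] * 2,
            small_grid,
            "2d",
        )
        assert pm2.sws[0, 0, 0] == pytest.approx(4.0 / 3.0, rel=1e-12)
        pm3 = km.compound_multifrequency(
            [np.full(shape, 1.3)] * 3, [np.full(shape, 0.9)] * 3, small_grid, "2d"
        )
        assert pm3.sws[0, 0, 0] == pytest.approx(1.3, rel=1e-12)

    def test_harmonic_not_above_arithmetic(self, small_grid):
        rng = np.random.default_rng(2)
        sws_f = [rng.uniform(0.8, 1.8, small_grid.shape) for _ in range(4)]
        pr_f = [np.ones(small_grid.shape)] * 4
        pm = km.compound_multifrequency(sws_f, pr_f, small_grid, "2d")
        arith = np.mean(sws_f, axis=0)
        assert np.all(pm.sws[pm.valid_mask] <= arith[pm.valid_mask] + 1e-12)


class TestTrimEdges:
    def _pmap(self, nz):
        g = km.AcquisitionGrid((8, 8, nz), SPACING, 8, (30.0,))
        ones = np.ones(g.shape)
        return km.ParameterMap(
            grid=g, sws=ones, pr=ones, valid_mask=np.ones(g.shape, bool), mode="2d"
        )

    def test_forty_slices_keep_thirtytwo(self):
        trimmed = km.trim_edges(self._pmap(40), 4)
        assert trimmed.n_valid_slices == 32
        assert not trimmed.valid_mask[:, :, :4].any()
        assert not trimmed.valid_mask[:, :, -4:].any()

    def test_zero_trim_is_identity(self):
        pm = self._pmap(12)
        out = km.trim_edges(pm, 0)
        assert out.n_valid_slices == 12

    def test_overtrim_rejected(self):
        with pytest.raises(ValueError, match="trim"):
            km.trim_edges(self._pmap(8), 4)


class TestPipelineProperties:
    def test_zero_field_rejected(self, small_grid):
        field = km.TimeSeriesField(
            grid=small_grid, data=np.zeros((1, 3, 8) + small_grid.shape)
        )
        with pytest.raises(ValueError, match="no wave energy"):
            km.run_pipeline(field, mode="2d")

    def test_scale_invariance(self, small_grid):
        field = plane_wave_field(small_grid, sws=1.2, pr=0.8)
        pm1 = km.run_pipeline(field, mode="2d", compound=CompoundConfig(trim_slices=1))
        scaled = km.TimeSeriesField(grid=small_grid, data=field.data * 7.5)
        pm2 = km.run_pipeline(scaled, mode="2d", compound=CompoundConfig(trim_slices=1))
        sel = pm1.valid_mask & pm2.valid_mask
        np.testing.assert_allclose(pm1.sws[sel], pm2.sws[sel], rtol=1e-5)
        np.testing.assert_allclose(pm1.pr[sel], pm2.pr[sel], rtol=1e-5)

    def test_frequency_consistency_nondispersive(self):
        """Same SWS at all four frequencies → compound equals single-frequency."""
        g4 = km.AcquisitionGrid((48, 48, 12), SPACING, 8, (20.0, 25.0, 30.0, 35.0))
        field = plane_wave_field(
            g4, sws=1.28, pr=0.9, propagation=(np.sqrt(0.5), np.sqrt(0.5), 0.0)
        )
        pm = km.run_pipeline(field, mode="2d", compound=CompoundConfig(trim_slices=2))
        box = np.zeros(g4.shape, bool)
        box[18:30, 18:30, :] = True
        sel = pm.valid_mask & box
        assert abs(np.nanmean(pm.sws[sel]) / 1.28 - 1) < 0.01

    def test_2d_3d_agree_for_inplane_wave(self, study_grid):
        """Purely in-plane propagation, identical across slices: the two
        pipelines agree on interior voxels."""
        field = plane_wave_field(
            study_grid, sws=1.28, pr=0.8,
            propagation=(np.sqrt(0.5), np.sqrt(0.5), 0.0),
        )
        box = np.zeros(study_grid.shape, bool)
        box[24:40, 24:40, :] = True
        means = {}
        for mode in ("2d", "3d"):
            pm = km.run_pipeline(field, mode=mode)
            means[mode] = np.nanmean(pm.sws[pm.valid_mask & box])
        assert abs(means["2d"] / means["3d"] - 1) < 0.03

    def test_brain_phantom_wm_recovery_2d(self, brain_phantom):
        """Noise-free brain-like phantom: WM mean within 5% of truth."""
        _, mask, field = brain_phantom
        pm = km.run_pipeline(field, mode="2d")
        mean, n = km.region_mean(pm, mask, 1)
        assert n > 1000
        assert abs(mean / 1.28 - 1) < 0.05


class TestSliceReduction:
    def test_bookkeeping_and_self_reference(self):
        g = km.AcquisitionGrid((32, 32, 13), SPACING, 8, (30.0,))
        spec, mask = km.reverberant_slab_phantom(g, seed=3)
        field = km.synthesize(spec)
        table = km.slice_reduction_experiment(field, mask, label=1, floor=9)
        assert list(table.n_slices) == [13, 11, 9]
        assert table.error_pct.iloc[0] == 0.0

    def test_even_slice_count_rejected(self, small_grid):
        field = plane_wave_field(small_grid)
        mask = km.RegionMask(
            labels=np.ones(small_grid.shape, np.int32), names={1: "WM"}
        )
        with pytest.raises(ValueError, match="odd"):
            km.slice_reduction_experiment(field, mask)
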