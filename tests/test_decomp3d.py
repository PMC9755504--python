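"""3D lowpass, curl operator, sphere directions, spherical decomposition."""

import numpy as np
import pytest

import kmdev as km
from kmdev.preprocess import extract_harmonic

from conftest import plane_wave_field


class TestLowpass3D:
    def test_dc_preserved_and_half_power(self, small_grid):
        data = np.ones((1, 3) + small_grid.shape, complex)
        cw = km.ComplexWaveField(grid=small_grid, data=data)
        out = km.lowpass3d(cw, order=1, cut=200.0)
        np.testing.assert_allclose(out.data, data, atol=1e-12)
        # half-power at the cut, evaluated from the response formula
        assert 1 / (1 + (200.0 / 200.0) ** 2) == pytest.approx(0.5)

    def test_in_band_wave_barely_attenuated(self, small_grid):
        # 30 Hz at 1.28 m/s → 23.4 cycles/m; H = 1/(1+(23.4/200)²) ≈ 0.9865
        field = plane_wave_field(small_grid, sws=1.28)
        cw = extract_harmonic(field)
        out = km.lowpass3d(cw, order=1, cut=200.0, pad="none")
        interior = np.s_[0, 2, 8:-8, 8:-8, :]
        ratio = np.abs(out.data[interior]).mean() / np.abs(cw.data[interior]).mean()
        assert ratio == pytest.approx(1 / (1 + (30.0 / 1.28 / 200.0) ** 2), abs=0.01)

    def test_rejects_bad_cut(self, small_grid):
        cw = km.ComplexWaveField(
            grid=small_grid, data=np.zeros((1, 3) + small_grid.shape, complex)
        )
        with pytest.raises(ValueError):
            km.lowpass3d(cw, cut=0.0)


class TestCurl3D:
    def test_curl_of_gradient_vanishes(self, small_grid):
        # u = ∇φ for a smooth low-frequency scalar φ
        X, Y, Z = small_grid.coords_m(sparse=False)
        kx, ky, kz = 40.0, 25.0, 30.0
        phi = np.sin(kx * X) * np.sin(ky * Y) * np.sin(kz * Z)
        h = small_grid.spacing_m
        u = np.stack(
            [np.gradient(phi, h[0], axis=0),
             np.gradient(phi, h[1], axis=1),
             np.gradient(phi, h[2], axis=2)]
        ).astype(complex)
        cw = km.ComplexWaveField(grid=small_grid, data=u[None])
        curl = km.curl3d(cw).data[0][:, 2:-2, 2:-2, 2:-2]
        scale = np.abs(u).max() * max(kx, ky, kz)
        assert np.abs(curl).max() < 5e-3 * scale  # O(h²) for analytic ∇φ

    def test_transverse_wave_curl_matches_discrete_derivative(self, small_grid):
        # u = (0, sin(kx), 0) → curl = (0, 0, k·cos(kx)) at stencil accuracy
        X, _, _ = small_grid.coords_m(sparse=False)
        k = 150.0
        u = np.zeros((3,) + small_grid.shape, complex)
        u[1] = np.sin(k * X)
        cw = km.ComplexWaveField(grid=small_grid, data=u[None])
        curl = km.curl3d(cw).data[0]
        h = small_grid.spacing_m[0]
        expected = (np.sin(k * h) / h) * np.cos(k * X)
        np.testing.assert_allclose(
            curl[2][1:-1], expected[1:-1], atol=1e-9 * k
        )
        assert np.abs(curl[0]).max() < 1e-12 and np.abs(curl[1]).max() < 1e-12

    def test_constant_field_zero_curl(self, small_grid):
        u = np.full((1, 3) + small_grid.shape, 2.0 + 1.0j)
        cw = km.ComplexWaveField(grid=small_grid, data=u)
        assert not np.any(km.curl3d(cw).data)


class TestSphereDirections:
    def test_dodecahedron_geometry(self):
        d = km.sphere_directions(20)
        assert d.shape == (20, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        # closed under negation
        for v in d:
            assert np.min(np.linalg.norm(d + v, axis=1)) < 1e-12
        # adjacent vertices of the dodecahedron: arccos(√5/3) ≈ 41.81°
        dots = d @ d.T
        np.fill_diagonal(dots, -1)
        assert np.degrees(np.arccos(dots.max())) == pytest.approx(41.8103, abs=1e-3)

    def test_fibonacci_fallback_and_floor(self):
        d = km.sphere_directions(12)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        with pytest.raises(ValueError):
            km.sphere_directions(5)


class TestDecomposeSpherical:
    @pytest.fixture(scope="class")
    def decomposed(self, small_grid):
        # propagate along a dodecahedron vertex direction
        v = km.sphere_directions(20)[16]
        p = np.cross(v, [0.0, 0.0, 1.0])
        p /= np.linalg.norm(p)
        field = plane_wave_field(small_grid, sws=1.2, propagation=tuple(v),
                                 polarization=tuple(p))
        cw = extract_harmonic(field)
        return cw, km.decompose_spherical(cw)

    def test_vertex_direction_dominates(self, decomposed):
        _, dec = decomposed
        energy = (np.abs(dec.data) ** 2).sum(axis=(1, 2, 3, 4, 5))
        assert int(np.argmax(energy)) == 16

    def test_partition_reconstructs_input(self, decomposed):
        cw, dec = decomposed
        total = dec.data.sum(axis=0)  # (component, frequency, voxel)
        for c in range(3):
            np.testing.assert_allclose(
                total[c, 0], cw.data[0, c], atol=1e-10 * np.abs(cw.data).max()
            )

    def test_zero_input_zero_output(self, small_grid):
        cw = km.ComplexWaveField(
            grid=small_grid, data=np.zeros((1, 3) + small_grid.shape, complex)
        )
        assert not np.any(km.decompose_spherical(cw).data)

    def test_rejects_small_grid(self):
        g = km.AcquisitionGrid((6, 6, 6), (1.6, 1.6, 2.0), 8, (30.0,))
        cw = km.ComplexWaveField(grid=g, data=np.zeros((1, 3) + g.shape, complex))
        with pytest.raises(ValueError, match="8 voxels"):
            km.decompose_spherical(cw)


class TestCompressionSuppression:
    def test_curl_removes_long_wavelength_compression(self, small_grid):
        """Curl of the synthetic curl-free contaminant is ~0 next to the
        curl of an equal-band shear wave (convergence checked at two
        resolutions in the synthetic module tests)."""
        comp = km.Compartment(mask=np.ones(small_grid.shape, bool), sws=1.2)
        shear = km.PhantomSpec(
            grid=small_grid,
            compartments=(comp,),
            sources=(
                km.ShearSource((1, 0, 0), (0, 0, 1), amplitude=10.0),
            ),
        )
        contaminated = km.PhantomSpec(
            grid=small_grid,
            compartments=(comp,),
            sources=shear.sources,
            compression=km.CompressionWave(amplitude=50.0, wavelength=1.0),
        )
        c_clean = km.curl3d(extract_harmonic(km.synthesize(shear)))
        c_dirty = km.curl3d(extract_harmonic(km.synthesize(contaminated)))
        diff = np.abs(c_dirty.data - c_clean.data)[..., 2:-2, 2:-2, 2:-2]
        ref = np.abs(c_clean.data)[..., 2:-2, 2:-2, 2:-2]
        assert diff.max() < 1e-3 * ref.max()
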