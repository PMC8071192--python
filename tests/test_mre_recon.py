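"""Unwrapping, harmonic extraction, curl and Helmholtz inversion."""

import math

import numpy as np
import pytest

from elastocomp.mre_recon import (CurlField, DisplacementField, central_roi,
                                  curl_field, displacement_from_acquisition,
                                  extract_harmonic, helmholtz_invert,
                                  reconstruct, roi_statistics, unwrap_phase)
from elastocomp.synthetic_data import AcquisitionGeometry, wrap_phase

from conftest import encode_to_acquisition, make_plane_wave


class TestUnwrapPhase:
    def test_wrapped_ramp_recovered_up_to_offset(self):
        true = np.linspace(0.0, 6 * math.pi, 400).reshape(20, 20)
        out = unwrap_phase(wrap_phase(true))
        diff = out - true
        # congruent modulo 2*pi, constant offset only
        assert np.allclose(diff, diff.flat[0], atol=1e-9)
        assert abs(diff.flat[0] / (2 * math.pi) - round(
            diff.flat[0] / (2 * math.pi))) < 1e-9

    def test_smooth_field_unchanged(self):
        rng = np.random.default_rng(0)
        field = 0.8 * np.sin(np.linspace(0, 3, 900)).reshape(30, 30)
        out = unwrap_phase(field)
        diff = out - field
        assert np.allclose(diff, diff.flat[0], atol=1e-9)

    def test_noisy_ramp_rmse(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.0, 6 * math.pi, 64)
        true = np.broadcast_to(x, (64, 64)) + rng.normal(0, 0.1, (64, 64))
        out = unwrap_phase(wrap_phase(true))
        out = out - (out - true).mean()    # global 2*pi*k offset
        rmse = math.sqrt(float(np.mean((out - true) ** 2)))
        assert rmse < 0.15

    def test_constant_input_returned(self):
        c = np.full((5, 5), 0.3)
        np.testing.assert_array_equal(unwrap_phase(c), c)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            unwrap_phase(np.full((4, 4), 3.5))


class TestExtractHarmonic:
    def test_dft_identity(self):
        amp, phi = 1.0, math.pi / 3
        m = np.arange(4)
        series = amp * np.cos(2 * math.pi * m / 4 + phi)[:, None, None] \
            * np.ones((4, 3, 3))
        out = extract_harmonic(series)
        # series = Re{A e^{2 i pi m/4}} with A = amp * e^{i phi}
        assert np.allclose(np.abs(out), amp)
        assert np.allclose(np.angle(out), phi)

    def test_dc_series_zero(self):
        series = np.full((4, 5, 5), 2.7)
        assert np.allclose(extract_harmonic(series), 0.0)

    def test_noise_averaging(self):
        rng = np.random.default_rng(2)
        m = np.arange(4)
        clean = np.cos(2 * math.pi * m / 4)[:, None] * np.ones((4, 20000))
        noisy = clean + rng.normal(0, 0.2, clean.shape)
        err = extract_harmonic(noisy) - extract_harmonic(clean)
        # each complex component has sd sigma*sqrt(2/N) = 0.2/sqrt(2);
        # |error| is then Rayleigh with mean sd*sqrt(pi/2)
        comp_sd = 0.2 * math.sqrt(2.0 / 4.0)
        assert np.std(err.real) == pytest.approx(comp_sd, rel=0.05)
        assert np.abs(err).mean() == pytest.approx(
            comp_sd * math.sqrt(math.pi / 2.0), rel=0.05)

    def test_too_few_offsets(self):
        with pytest.raises(ValueError, match="3 offsets"):
            extract_harmonic(np.zeros((2, 4, 4)))

    def test_encoding_efficiency_scaling(self):
        m = np.arange(4)
        series = np.cos(2 * math.pi * m / 4)[:, None] * np.ones((4, 3))
        out = extract_harmonic(series, encoding_efficiency=2.0)
        assert np.allclose(np.abs(out), 0.5)


class TestCurlField:
    def test_constant_field_zero_curl(self, geometry_small):
        u = np.ones((3,) + geometry_small.shape, dtype=complex)
        c = curl_field(DisplacementField(values=u, geometry=geometry_small))
        assert np.allclose(c.values, 0.0)

    def test_gradient_field_is_irrotational(self, geometry_small):
        nz, ny, nx = geometry_small.shape
        dz, dy, dx = geometry_small.spacing_um
        Z, Y, X = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                              np.arange(nx) * dx, indexing="ij")
        L = 40 * 300.0
        phi = np.exp(-((X - X.mean()) ** 2 + (Y - Y.mean()) ** 2
                       + (Z - Z.mean()) ** 2) / (2 * L ** 2))
        g = np.gradient(phi, dz, dy, dx)
        u = np.stack([g[2], g[1], g[0]]).astype(complex)
        c = curl_field(DisplacementField(values=u, geometry=geometry_small))
        v = c.validity_mask
        scale = np.abs(np.stack(g)).max()
        assert np.abs(c.values[:, v]).max() < 1e-6 * scale / 300.0 * 300.0

    def test_plane_wave_curl_amplitude(self, geometry):
        """|q| = |k x u| for a transverse plane wave, to 2nd-order accuracy."""
        u, k, n_hat = make_plane_wave(geometry, 3.0 + 0.0001j)
        c = curl_field(DisplacementField(values=u, geometry=geometry))
        v = c.validity_mask
        qmag = np.sqrt((np.abs(c.values) ** 2).sum(axis=0))
        umag = np.sqrt((np.abs(u) ** 2).sum(axis=0))
        ratio = np.median(qmag[v] / (abs(k) * umag[v]))
        # the central difference attenuates each derivative by sin(kh)/(kh);
        # the exact 2nd-order factor lies between the worst single-axis
        # attenuation and 1
        h_max = max(geometry.spacing_um)
        worst = math.sin(abs(k) * h_max) / (abs(k) * h_max)
        assert worst * 0.995 <= ratio <= 1.0

    def test_too_small_grid(self):
        geom = AcquisitionGeometry(matrix_rows=8, matrix_cols=8, n_slices=2)
        u = np.zeros((3,) + geom.shape, dtype=complex)
        with pytest.raises(ValueError, match="3 voxels"):
            curl_field(DisplacementField(values=u, geometry=geom))


class TestHelmholtzInversion:
    @pytest.mark.parametrize("gp", [1.0, 2.0, 4.0])
    @pytest.mark.parametrize("gpp", [0.5, 1.0, 2.0])
    def test_dispersion_oracle_grid(self, geometry, gp, gpp):
        """Noise-free plane wave: recovered moduli within 2% of the
        dispersion-relation truth G* = rho omega^2 / k^2."""
        u, _, _ = make_plane_wave(geometry, complex(gp, gpp))
        acq = encode_to_acquisition(u, geometry)
        stats = roi_statistics(reconstruct(acq), central_roi(geometry))
        assert stats.mean_storage_kpa == pytest.approx(gp, rel=0.02)
        assert stats.mean_loss_kpa == pytest.approx(gpp, rel=0.02)

    def test_scale_invariance(self, geometry):
        """G* is a ratio: scaling the curl by any complex constant is
        irrelevant."""
        u, _, _ = make_plane_wave(geometry, 2.0 + 1.0j)
        c = curl_field(DisplacementField(values=u, geometry=geometry))
        m1 = helmholtz_invert(c)
        c2 = CurlField(values=c.values * (2.0 + 3.0j),
                       validity_mask=c.validity_mask, geometry=geometry)
        m2 = helmholtz_invert(c2)
        np.testing.assert_allclose(m1.storage_modulus, m2.storage_modulus,
                                   rtol=1e-9, atol=1e-12)
        np.testing.assert_array_equal(m1.validity_mask, m2.validity_mask)

    def test_linear_region_masked_not_infinite(self, geometry_small):
        """Voxels where q is linear in space (zero Laplacian) are masked."""
        nz, ny, nx = geometry_small.shape
        u, _, _ = make_plane_wave(geometry_small, 2.0 + 1.0j)
        c = curl_field(DisplacementField(values=u, geometry=geometry_small))
        vals = c.values.copy()
        X = np.arange(nx) * 1.0
        vals[:, :, :, nx // 2:] = (0.001 * X[nx // 2:] + 0.5)[None, None, None]
        c2 = CurlField(values=vals, validity_mask=c.validity_mask,
                       geometry=geometry_small)
        maps = helmholtz_invert(c2, smooth_sigma_vox=0.0,
                                smooth_sigma_slices=0.0, amplitude_floor=0.0)
        linear_zone = np.zeros(geometry_small.shape, dtype=bool)
        linear_zone[2:-2, 6:-6, nx // 2 + 4:-6] = True
        assert not maps.validity_mask[linear_zone].any()
        assert np.all(np.isfinite(maps.storage_modulus))

    def test_amplitude_doubling_leaves_gstar(self, geometry):
        """Pipeline is linear through harmonic extraction: doubling the
        displacement amplitude leaves G* unchanged."""
        u, _, _ = make_plane_wave(geometry, 2.0 + 1.0j)
        s1 = roi_statistics(reconstruct(encode_to_acquisition(u, geometry, 0.15)),
                            central_roi(geometry))
        s2 = roi_statistics(reconstruct(encode_to_acquisition(u, geometry, 0.30)),
                            central_roi(geometry))
        assert s1.mean_storage_kpa == pytest.approx(s2.mean_storage_kpa,
                                                    rel=1e-3)
        assert s1.mean_loss_kpa == pytest.approx(s2.mean_loss_kpa, rel=1e-3)

    def test_compressional_insensitivity(self, geometry):
        """An irrotational field of equal amplitude changes G* by < 3%."""
        u, _, _ = make_plane_wave(geometry, 3.0 + 1.0j)
        nz, ny, nx = geometry.shape
        dz, dy, dx = geometry.spacing_um
        Z, Y, X = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                              np.arange(nx) * dx, indexing="ij")
        kc = 2 * math.pi / (30 * 300.0)    # long compressional wavelength
        phi = np.exp(-1j * kc * (0.6 * X + 0.8 * Y))
        g = np.gradient(phi, dz, dy, dx)
        comp = np.stack([g[2], g[1], g[0]])
        comp = comp / np.abs(comp).max() * np.abs(u).max()
        ref = roi_statistics(reconstruct(encode_to_acquisition(u, geometry)),
                             central_roi(geometry))
        mixed = roi_statistics(
            reconstruct(encode_to_acquisition(u + comp, geometry)),
            central_roi(geometry))
        assert mixed.mean_storage_kpa == pytest.approx(
            ref.mean_storage_kpa, rel=0.03)
        assert mixed.mean_loss_kpa == pytest.approx(
            ref.mean_loss_kpa, rel=0.03)

    def test_mask_soundness_under_noise(self, geometry_small, hcc_subject):
        from elastocomp.synthetic_data import simulate_wave_acquisition
        acq = simulate_wave_acquisition(hcc_subject, 0.0, geometry_small,
                                        seed=8, noise_sd=0.05)
        maps = reconstruct(acq)
        v = maps.validity_mask
        assert np.all(np.isfinite(maps.storage_modulus[v]))
        assert np.all(np.isfinite(maps.loss_modulus[v]))
        assert np.all(maps.storage_modulus[v] > 0)
        assert np.all(maps.loss_modulus[v] >= 0)

    def test_invalid_parameters(self, geometry_small):
        u, _, _ = make_plane_wave(geometry_small, 2.0 + 1.0j)
        c = curl_field(DisplacementField(values=u, geometry=geometry_small))
        with pytest.raises(ValueError):
            helmholtz_invert(c, stability_floor=-1.0)
        with pytest.raises(ValueError):
            helmholtz_invert(c, density=-5.0)


class TestRoiStatistics:
    def _uniform_maps(self, geometry, gp=1.6, gpp=1.0):
        from elastocomp.mre_recon import ElastogramMaps
        shape = geometry.shape
        return ElastogramMaps(
            storage_modulus=np.full(shape, gp),
            loss_modulus=np.full(shape, gpp),
            validity_mask=np.ones(shape, dtype=bool),
            clamped_mask=np.zeros(shape, dtype=bool),
            density=1000.0, angular_frequency=2 * math.pi * 600)

    def test_uniform_map_mean(self, geometry_small):
        maps = self._uniform_maps(geometry_small)
        roi = np.ones(geometry_small.shape, dtype=bool)
        st = roi_statistics(maps, roi)
        assert st.mean_storage_kpa == pytest.approx(1.6)

    def test_only_central_slices_contribute(self, geometry_small):
        maps = self._uniform_maps(geometry_small)
        # poison the outer slices: a 9-slice stack must only use slices 2..6
        maps.storage_modulus[[0, 1, 7, 8]] = 99.0
        roi = np.ones(geometry_small.shape, dtype=bool)
        st = roi_statistics(maps, roi)
        assert st.mean_storage_kpa == pytest.approx(1.6)

    def test_half_masked_roi(self, geometry_small):
        maps = self._uniform_maps(geometry_small)
        st_full = roi_statistics(maps, np.ones(geometry_small.shape, bool))
        ny = geometry_small.shape[1]
        maps.validity_mask[:, ny // 2:, :] = False
        maps.storage_modulus[:, ny // 2:, :] = 99.0
        st_half = roi_statistics(maps, np.ones(geometry_small.shape, bool))
        assert st_half.mean_storage_kpa == pytest.approx(1.6)
        assert st_half.n_voxels < st_full.n_voxels

    def test_empty_roi_raises(self, geometry_small):
        maps = self._uniform_maps(geometry_small)
        maps.validity_mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            roi_statistics(maps, np.ones(geometry_small.shape, bool))
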