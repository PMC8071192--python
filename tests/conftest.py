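import math

import numpy as np
import pytest

from elastocomp.synthetic_data import (AcquisitionGeometry, CohortConfig,
                                       SubjectTruth, WaveAcquisition,
                                       shear_wavenumber, wrap_phase)


@pytest.fixture
def geometry():
    """Full study acquisition geometry."""
    return AcquisitionGeometry()


@pytest.fixture
def geometry_small():
    """Reduced in-plane matrix for fast reconstruction tests."""
    return AcquisitionGeometry(matrix_rows=48, matrix_cols=40)


@pytest.fixture
def hcc_subject():
    return SubjectTruth("HCC-T1", "HCC", 10.7, 2.3, 726.0, 1.1, 252.0,
                        basal_elasticity=1.6, basal_viscosity=1.1,
                        stiffening_slope=0.6)


@pytest.fixture
def cca_subject():
    return SubjectTruth("CCA-T1", "CCA", 15.8, 2.3, 809.0, 3.6, 233.0,
                        basal_elasticity=2.2, basal_viscosity=1.8,
                        stiffening_slope=0.8)


@pytest.fixture
def default_config():
    return CohortConfig()


def make_plane_wave(geometry, gstar_kpa, az_deg=25.0, el_deg=10.0,
                    pol=(0.8, 0.6), amplitude=1.0):
    """Analytic transverse plane wave on the acquisition grid.

    Returns (displacement values [3, z, y, x], complex wavenumber 1/µm,
    propagation direction).
    """
    nz, ny, nx = geometry.shape
    dz, dy, dx = geometry.spacing_um
    Z, Y, X = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                          np.arange(nx) * dx, indexing="ij")
    k = shear_wavenumber(gstar_kpa, geometry.vibration_frequency_hz)
    el, az = math.radians(el_deg), math.radians(az_deg)
    n_hat = np.array([math.cos(el) * math.cos(az),
                      math.cos(el) * math.sin(az), math.sin(el)])
    e1 = np.cross(n_hat, [0.0, 0.0, 1.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_hat, e1)
    p_hat = pol[0] * e2 + pol[1] * e1
    s = n_hat[0] * X + n_hat[1] * Y + n_hat[2] * Z
    u = amplitude * p_hat[:, None, None, None] \
        * np.exp(-1j * k * (s - s.min()))[None]
    return u, k, n_hat


def encode_to_acquisition(u, geometry, amp_scale=0.3, noise_sd=0.0, rng=None):
    """Motion-encode a complex displacement field into wrapped phases."""
    eff = geometry.encoding_efficiency_rad_per_um
    phases = np.empty((3, geometry.n_offsets) + geometry.shape)
    for d in range(3):
        enc = eff * u[d] * amp_scale
        for m in range(geometry.n_offsets):
            snap = np.real(enc * np.exp(2j * math.pi * m / geometry.n_offsets))
            if noise_sd > 0:
                snap = snap + rng.normal(0.0, noise_sd, snap.shape)
            phases[d, m] = snap
    return WaveAcquisition(geometry=geometry, wrapped_phase=wrap_phase(phases),
                           noise_sd=noise_sd)
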