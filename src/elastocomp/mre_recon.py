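"""Viscoelastic reconstruction from wrapped-phase wave images.

Pipeline: per-image phase unwrapping -> temporal harmonic extraction over the
acquisition offsets -> complex displacement field -> curl (suppresses the
compressional, irrotational wave component) -> Gaussian smoothing -> local
Helmholtz inversion

    G* = -rho * omega^2 * q / laplacian(q),

combining the three curl components by a magnitude-weighted average.  The
storage modulus G' (elasticity) is Re(G*), the loss modulus G'' (viscosity) is
Im(G*), both in kPa.

Numerical notes: the in-plane Laplacian uses a fourth-order central stencil
(the second-order stencil underestimates the curvature of a wave sampled at
6-8 voxels per wavelength by 7-10%, well above the accuracy target of the
inversion); the through-plane stencil is second order, which keeps the
through-plane validity border at one slice so the five central slices of a
nine-slice acquisition all remain usable.  Plane waves are eigenfunctions of
both convolution smoothing and the discrete Laplacian, so smoothing does not
bias the modulus ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap

from .synthetic_data import (AcquisitionGeometry, TISSUE_DENSITY,
                             WaveAcquisition)

__all__ = [
    "DisplacementField",
    "CurlField",
    "ElastogramMaps",
    "RoiStatistics",
    "unwrap_phase",
    "extract_harmonic",
    "displacement_from_acquisition",
    "curl_field",
    "helmholtz_invert",
    "reconstruct",
    "roi_statistics",
    "central_roi",
]


@dataclass
class DisplacementField:
    """Complex harmonic displacement, µm, components (x, y, z) on axis 0,
    spatial axes (slice, row, col)."""

    values: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if self.values.shape != (3,) + self.geometry.shape:
            raise ValueError("displacement shape inconsistent with geometry")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("displacement field contains non-finite values")


@dataclass
class CurlField:
    """Complex curl of the displacement field (dimensionless, µm/µm)."""

    values: np.ndarray
    validity_mask: np.ndarray
    geometry: AcquisitionGeometry


@dataclass
class ElastogramMaps:
    """Per-voxel storage and loss moduli with a validity mask.

    ``clamped_mask`` flags voxels where a (non-physical) negative loss modulus
    was clamped to zero.
    """

    storage_modulus: np.ndarray      # G', kPa
    loss_modulus: np.ndarray         # G'', kPa
    validity_mask: np.ndarray
    clamped_mask: np.ndarray
    density: float                   # kg/m^3
    angular_frequency: float         # rad/s


@dataclass
class RoiStatistics:
    mean_storage_kpa: float
    mean_loss_kpa: float
    n_voxels: int


# --------------------------------------------------------------------------
# unwrapping and harmonic extraction
# --------------------------------------------------------------------------

def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Unwrap a 2-D or 3-D wrapped-phase image (reliability-sorting method).

    The result is congruent to the input modulo 2*pi at every voxel, up to a
    global 2*pi*k offset.  Constant images are returned unchanged.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if wrapped.min() < -math.pi or wrapped.max() >= math.pi:
        raise ValueError("input must be wrapped to [-pi, pi)")
    if np.ptp(wrapped) == 0:
        return wrapped.copy()
    out = _unwrap(wrapped)
    return np.asarray(out, dtype=float)


def extract_harmonic(offset_series: np.ndarray,
                     n_offsets: int | None = None,
                     encoding_efficiency: float = 1.0) -> np.ndarray:
    """Fundamental-frequency complex amplitude over the offset dimension.

    ``offset_series`` has the offset axis first and must already be unwrapped;
    the offsets are assumed to sample one vibration period evenly.  Returns
    the complex amplitude ``A`` such that the series is
    ``Re{A * exp(2i*pi*m/N)}``, converted to µm by ``encoding_efficiency``
    (rad/µm).
    """
    series = np.asarray(offset_series, dtype=float)
    n = series.shape[0] if n_offsets is None else n_offsets
    if n < 3:
        raise ValueError(
            "at least 3 offsets are required to identify the fundamental")
    if series.shape[0] != n:
        raise ValueError("offset axis length inconsistent with n_offsets")
    m = np.arange(n)
    kernel = np.exp(-2j * math.pi * m / n)
    amp = (2.0 / n) * np.tensordot(kernel, series, axes=(0, 0))
    return amp / encoding_efficiency


def displacement_from_acquisition(acq: WaveAcquisition) -> DisplacementField:
    """Unwrap every phase image, remove its spatial mean (the global 2*pi*k
    ambiguity of unwrapping; any spatially constant error is annihilated by
    the curl anyway) and extract the harmonic per encoding direction."""
    geom = acq.geometry
    n_off = geom.n_offsets
    encoded = np.empty((3,) + geom.shape, dtype=complex)
    for d in range(3):
        unwrapped = np.empty((n_off,) + geom.shape)
        for m in range(n_off):
            u = unwrap_phase(acq.wrapped_phase[d, m])
            unwrapped[m] = u - u.mean()
        encoded[d] = extract_harmonic(
            unwrapped, n_off, geom.encoding_efficiency_rad_per_um)
    # project measured components back onto the lab frame
    E = geom.encoding_directions
    values = np.tensordot(E.T, encoded, axes=(1, 0))
    return DisplacementField(values=values, geometry=geom)


# --------------------------------------------------------------------------
# curl and Laplacian
# --------------------------------------------------------------------------

def curl_field(displacement: DisplacementField) -> CurlField:
    """Central-difference curl with per-axis spacing; the one-voxel border
    (one-sided differences) is marked invalid."""
    geom = displacement.geometry
    if min(geom.shape) < 3:
        raise ValueError("need at least 3 voxels along every axis")
    dz, dy, dx = geom.spacing_um
    u = displacement.values   # (component x/y/z, z, y, x)
    dux = np.gradient(u[0], dz, dy, dx, edge_order=2)
    duy = np.gradient(u[1], dz, dy, dx, edge_order=2)
    duz = np.gradient(u[2], dz, dy, dx, edge_order=2)
    curl = np.stack([
        duz[1] - duy[0],   # dUz/dy - dUy/dz
        dux[0] - duz[2],   # dUx/dz - dUz/dx
        duy[2] - dux[1],   # dUy/dx - dUx/dy
    ])
    valid = np.zeros(geom.shape, dtype=bool)
    valid[1:-1, 1:-1, 1:-1] = True
    return CurlField(values=curl, validity_mask=valid, geometry=geom)


def _laplacian(field: np.ndarray,
               spacing: tuple[float, float, float],
               inplane_margin: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Anisotropic Laplacian: 4th-order in-plane, 2nd-order through-plane.

    Validity excludes ``inplane_margin`` voxels in-plane (at least the 2 the
    stencil needs; wider when upstream smoothing has mixed border values
    inward) and 2 slices through-plane (one for the curl border, one for the
    stencil — the rationale for summarizing over the central slices only).
    """
    dz, dy, dx = spacing
    m = max(2, inplane_margin)
    lap = np.zeros_like(field)
    # through-plane, 2nd order
    lap[1:-1] += (field[2:] - 2.0 * field[1:-1] + field[:-2]) / dz ** 2
    # in-plane, 4th order: (-f[i+2] + 16 f[i+1] - 30 f[i] + 16 f[i-1] - f[i-2]) / 12h^2
    lap[:, 2:-2] += (-field[:, 4:] + 16 * field[:, 3:-1] - 30 * field[:, 2:-2]
                     + 16 * field[:, 1:-3] - field[:, :-4]) / (12.0 * dy ** 2)
    lap[:, :, 2:-2] += (-field[:, :, 4:] + 16 * field[:, :, 3:-1]
                        - 30 * field[:, :, 2:-2] + 16 * field[:, :, 1:-3]
                        - field[:, :, :-4]) / (12.0 * dx ** 2)
    valid = np.zeros(field.shape, dtype=bool)
    if field.shape[0] > 4 and field.shape[1] > 2 * m and field.shape[2] > 2 * m:
        valid[2:-2, m:-m, m:-m] = True
    else:
        valid[1:-1, 2:-2, 2:-2] = True
    return lap, valid


def helmholtz_invert(curl: CurlField,
                     density: float = TISSUE_DENSITY,
                     angular_frequency: float | None = None,
                     stability_floor: float = 1e-3,
                     smooth_sigma_vox: float = 2.0,
                     smooth_sigma_slices: float = 0.8,
                     amplitude_floor: float = 0.05) -> ElastogramMaps:
    """Per-voxel algebraic Helmholtz inversion of the curl field.

    Per curl component i with |lap(q_i)| above the stability floor (a
    relative threshold on the grid median), ``G_i* = -rho omega^2 q_i /
    lap(q_i)``; components are combined by a magnitude-weighted average with
    weights ``|lap(q_i)|^2``.  Voxels with no admissible component are masked.
    Negative loss moduli are clamped to zero and flagged.

    ``amplitude_floor`` is a confidence mask for attenuating media: voxels
    whose total curl magnitude falls below this fraction of the 95th
    percentile carry too little wave signal for a stable ratio and are marked
    invalid (shear waves at hundreds of Hz in lossy tissue decay within a few
    wavelengths, leaving parts of the field of view without usable signal).
    """
    if stability_floor < 0:
        raise ValueError("stability floor must be >= 0")
    if density <= 0:
        raise ValueError("density must be positive")
    geom = curl.geometry
    omega = geom.angular_frequency if angular_frequency is None \
        else angular_frequency
    if omega <= 0:
        raise ValueError("angular frequency must be positive")
    spacing_m = tuple(s * 1e-6 for s in geom.spacing_um)

    # smoothing is in-plane only: through-plane the stack is thin (9 slices)
    # and smoothing would mix the one-sided-difference border slices into the
    # central ones; in-plane the contaminated margin is excluded below
    q = curl.values
    if smooth_sigma_vox > 0 or smooth_sigma_slices > 0:
        sig = (0, smooth_sigma_slices, smooth_sigma_vox, smooth_sigma_vox)
        q = (ndimage.gaussian_filter(q.real, sig)
             + 1j * ndimage.gaussian_filter(q.imag, sig))
    inplane_margin = 2 + int(math.ceil(2.0 * smooth_sigma_vox))

    qmag = np.sqrt(np.sum(np.abs(q) ** 2, axis=0))
    amp_ok = np.ones(geom.shape, dtype=bool)
    if amplitude_floor > 0:
        ref = np.percentile(qmag[curl.validity_mask], 95)
        amp_ok = qmag >= amplitude_floor * ref

    num = np.zeros(geom.shape, dtype=complex)
    den = np.zeros(geom.shape)
    any_admissible = np.zeros(geom.shape, dtype=bool)
    for i in range(3):
        lap, lap_valid = _laplacian(q[i], spacing_m, inplane_margin)
        base = curl.validity_mask & lap_valid & amp_ok
        mag = np.abs(lap)
        if not base.any():
            raise ValueError("no valid voxels for inversion")
        floor = stability_floor * np.median(mag[base])
        admissible = base & (mag > floor)
        gi = np.zeros(geom.shape, dtype=complex)
        gi[admissible] = -density * omega ** 2 * q[i][admissible] / lap[admissible]
        w = mag ** 2
        num[admissible] += (w * gi)[admissible]
        den[admissible] += w[admissible]
        any_admissible |= admissible

    valid = any_admissible & (den > 0)
    if not valid.any():
        raise ValueError("no valid voxels for inversion")
    gstar = np.zeros(geom.shape, dtype=complex)
    gstar[valid] = num[valid] / den[valid]
    storage = np.where(valid, gstar.real, 0.0) / 1e3    # Pa -> kPa
    loss = np.where(valid, gstar.imag, 0.0) / 1e3
    valid &= storage > 0
    clamped = valid & (loss < 0)
    loss[clamped] = 0.0
    storage[~valid] = 0.0
    loss[~valid] = 0.0
    return ElastogramMaps(storage_modulus=storage, loss_modulus=loss,
                          validity_mask=valid, clamped_mask=clamped,
                          density=density, angular_frequency=omega)


def reconstruct(acq: WaveAcquisition,
                density: float = TISSUE_DENSITY,
                stability_floor: float = 1e-3,
                smooth_sigma_vox: float = 2.0,
                smooth_sigma_slices: float = 0.8,
                amplitude_floor: float = 0.05) -> ElastogramMaps:
    """Full chain: unwrap -> harmonic -> curl -> smoothed Helmholtz inversion."""
    disp = displacement_from_acquisition(acq)
    curl = curl_field(disp)
    return helmholtz_invert(curl, density=density,
                            stability_floor=stability_floor,
                            smooth_sigma_vox=smooth_sigma_vox,
                            smooth_sigma_slices=smooth_sigma_slices,
                            amplitude_floor=amplitude_floor)


# --------------------------------------------------------------------------
# ROI summaries
# --------------------------------------------------------------------------

def central_roi(geometry: AcquisitionGeometry,
                fraction: float = 0.75) -> np.ndarray:
    """Elliptical in-plane ROI covering ``fraction`` of each dimension,
    through all slices — a stand-in for the manually drawn tumor ROI."""
    nz, ny, nx = geometry.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    ell = (((yy - (ny - 1) / 2) / (fraction * ny / 2)) ** 2
           + ((xx - (nx - 1) / 2) / (fraction * nx / 2)) ** 2) <= 1.0
    return np.broadcast_to(ell, (nz, ny, nx)).copy()


def roi_statistics(maps: ElastogramMaps,
                   roi_mask: np.ndarray,
                   n_central_slices: int = 5) -> RoiStatistics:
    """Mean G' and G'' over the ROI, restricted to the central slices.

    The ROI is eroded by one in-plane voxel (border avoidance), intersected
    with the validity mask, and restricted to the ``n_central_slices`` central
    slices (slices 3-7 of 9, 1-based).
    """
    if roi_mask.shape != maps.storage_modulus.shape:
        raise ValueError("roi_mask must match the map grid")
    nz = roi_mask.shape[0]
    roi = ndimage.binary_erosion(roi_mask,
                                 structure=np.ones((1, 3, 3), dtype=bool))
    if nz > n_central_slices:
        lo = (nz - n_central_slices) // 2
        slab = np.zeros_like(roi)
        slab[lo:lo + n_central_slices] = True
        roi &= slab
    eff = roi & maps.validity_mask
    n = int(eff.sum())
    if n == 0:
        raise ValueError("effective ROI is empty")
    return RoiStatistics(
        mean_storage_kpa=float(maps.storage_modulus[eff].mean()),
        mean_loss_kpa=float(maps.loss_modulus[eff].mean()),
        n_voxels=n,
    )
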