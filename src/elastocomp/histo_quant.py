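"""Digital histology quantification.

Collagen fraction from picrosirius-red tiles by colour deconvolution of the
RGB image and thresholding of the red-stain channel, expressed as a percent
of the tissue area (background excluded by brightness).  Cellularity from
nucleus-stained fields by Otsu thresholding followed by a distance-transform
watershed that splits touching nuclei, expressed as nuclei per mm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, separate_stains
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .synthetic_data import (HistologySlide, PICRO_BACKGROUND_RGB,
                             PICRO_COLLAGEN_RGB, PICRO_TISSUE_RGB)

__all__ = ["QuantResult", "collagen_fraction", "count_nuclei",
           "default_stain_matrix"]


@dataclass
class QuantResult:
    """Result of one tile quantification."""

    collagen_fraction: float | None = None   # % of tissue area
    cell_density: float | None = None        # cells/mm^2
    n_objects: int = 0
    tissue_area_mm2: float = 0.0

    def __post_init__(self) -> None:
        if self.collagen_fraction is not None and not \
                0.0 <= self.collagen_fraction <= 100.0:
            raise ValueError("collagen fraction must be in [0, 100]")
        if self.n_objects < 0:
            raise ValueError("counts must be >= 0")
        if self.tissue_area_mm2 <= 0:
            raise ValueError("tissue area must be positive")


def _od_vector(rgb: tuple[int, int, int]) -> np.ndarray:
    """Optical-density vector of a stain colour, unit normalized."""
    od = -np.log10((np.asarray(rgb, float) + 1.0) / 256.0)
    return od / np.linalg.norm(od)


def default_stain_matrix() -> np.ndarray:
    """Stain OD matrix (rows: picrosirius red, eosin-like counterstain,
    residual) matched to the renderer palette; override for other palettes."""
    v1 = _od_vector(PICRO_COLLAGEN_RGB)
    v2 = _od_vector(PICRO_TISSUE_RGB)
    v3 = np.cross(v1, v2)
    v3 /= np.linalg.norm(v3)
    return np.array([v1, v2, v3])


BACKGROUND_LUMINANCE = 0.93   # of 1.0; renderer background is near-white


def _deconvolved_red_od(rgb: tuple[int, int, int], M: np.ndarray) -> float:
    """Red-stain channel value of a single colour under the stain matrix."""
    px = np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3)
    return float(separate_stains(px, np.linalg.inv(M))[0, 0, 0])


def _stain_floor(M: np.ndarray) -> float:
    """Minimum red-stain OD counted as collagen: one quarter of the way from
    the pure counterstain colour to the pure stain colour."""
    lo = _deconvolved_red_od(PICRO_TISSUE_RGB, M)
    hi = _deconvolved_red_od(PICRO_COLLAGEN_RGB, M)
    return lo + 0.25 * (hi - lo)


def _drop_small(binary: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndimage.label(binary)
    if n == 0:
        return binary
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]


def collagen_fraction(slide: HistologySlide,
                      stain_matrix: np.ndarray | None = None,
                      threshold: float | None = None) -> QuantResult:
    """Collagen fraction (%) of the tissue area of a picrosirius tile.

    Colour deconvolution separates the red stain from the counterstain; the
    red-stain optical-density channel is thresholded (Otsu over the tissue by
    default, or a fixed OD ``threshold``).
    """
    if slide.stain != "picrosirius":
        raise ValueError("collagen_fraction requires a picrosirius slide")
    img = slide.pixels
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("picrosirius slide must be RGB")
    if slide.pixel_size_um is None:
        raise ValueError("pixel size is required")

    lum = rgb2gray(img)
    tissue = lum < BACKGROUND_LUMINANCE
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask (all-background tile)")

    M = default_stain_matrix() if stain_matrix is None else stain_matrix
    stains = separate_stains(img, np.linalg.inv(M))
    red_od = stains[..., 0]
    vals = red_od[tissue]
    if threshold is None:
        # Otsu over the tissue, guarded by a palette-derived floor so a tile
        # with no stained pixels at all is not split on counterstain noise
        floor = _stain_floor(M)
        threshold = max(float(threshold_otsu(vals)), floor)
    stained = tissue & (red_od > threshold)
    area_mm2 = n_tissue * (slide.pixel_size_um * 1e-3) ** 2
    frac = 100.0 * float(stained.sum()) / n_tissue
    return QuantResult(collagen_fraction=frac,
                       n_objects=int(label(stained).max()),
                       tissue_area_mm2=area_mm2)


def count_nuclei(slide: HistologySlide,
                 min_area_um2: float = 25.0,
                 marker_min_distance_um: float = 5.0) -> QuantResult:
    """Count nuclei and return the cell density of a nucleus-stained field.

    Global Otsu threshold -> small-object removal -> distance-transform
    watershed with peak markers (splits touching nuclei) -> objects below the
    minimum-area floor discarded.  The density denominator is the full field
    area (nucleus-stained snapshots are acquired inside the tissue).
    """
    if slide.stain != "nucleus":
        raise ValueError("count_nuclei requires a nucleus-stained slide")
    if slide.pixel_size_um is None:
        raise ValueError("pixel size is required (density undefined)")
    img = slide.pixels
    if img.ndim == 3:
        img = (rgb2gray(img) * 255.0)
    img = img.astype(float)

    area_mm2 = img.size * (slide.pixel_size_um * 1e-3) ** 2
    if img.max() == img.min():
        return QuantResult(cell_density=0.0, n_objects=0,
                           tissue_area_mm2=area_mm2)
    thresh = threshold_otsu(img)
    binary = img > thresh
    # contrast guard: an empty field must not be split on background noise
    bg = img[~binary]
    if binary.any() and bg.size and \
            img[binary].mean() - bg.mean() < 6.0 * max(bg.std(), 1e-6):
        binary[:] = False
    min_area_px = max(1, int(round(min_area_um2 / slide.pixel_size_um ** 2)))
    binary = _drop_small(binary, min_area_px)
    if not binary.any():
        return QuantResult(cell_density=0.0, n_objects=0,
                           tissue_area_mm2=area_mm2)

    distance = ndimage.distance_transform_edt(binary)
    min_dist_px = max(2, int(round(marker_min_distance_um / slide.pixel_size_um)))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=binary,
                           exclude_border=False)
    markers = np.zeros(binary.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=binary)
    count = sum(1 for p in regionprops(labels) if p.area >= min_area_px)
    return QuantResult(cell_density=count / area_mm2, n_objects=count,
                       tissue_area_mm2=area_mm2)
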