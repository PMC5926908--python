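"""Tissue/background segmentation of brightfield slides.

The stage reproduces a fixed-threshold segmentation scheme designed for
8-bit brightfield histology: a darkest-channel composite is mean-filtered
with a 25 x 25 window, thresholded at the 99th centile minus 15 grey
levels (tissue being the darker side of a transmitted-light image),
refined against the 10th centile of the background minus 10, and cleaned
by two area rules — islands of tissue or background under 50 um^2 are
flipped to the surrounding class, then tissue components under 1% of the
total tissue area are dropped. Regions of interest default to a 2 x 2
split of the tissue bounding box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .config import TissueConfig

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Invalid input data (maps to exit code 2 in the CLI)."""


@dataclass(frozen=True)
class Slide:
    """An 8-bit RGB raster with a physical pixel size.

    Every area threshold in the pipeline is defined in um^2 against
    ``pixel_size_um`` (micrometers per pixel edge).
    """

    rgb: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise DataError("Slide.rgb must be an (H, W, 3) raster")
        if rgb.dtype != np.uint8:
            raise DataError("Slide.rgb must be 8-bit (uint8)")
        if not self.pixel_size_um > 0:
            raise DataError("pixel_size_um must be > 0")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


def darkest_channel(slide: Slide) -> np.ndarray:
    """Per-pixel minimum over the three colour channels (float raster)."""
    return slide.rgb.min(axis=2).astype(float)


def mean_filter(raster: np.ndarray, window_px: int) -> np.ndarray:
    """Sliding-window mean with the value assigned to the central pixel.

    The window must be odd; borders are handled by reflection padding so
    that edge means are not biased toward darkness (which would distort
    the percentile thresholds downstream).
    """
    if window_px < 1 or window_px % 2 == 0:
        raise ValueError("mean filter window must be odd and >= 1")
    return ndi.uniform_filter(np.asarray(raster, dtype=float), size=window_px, mode="reflect")


def initial_tissue_mask(filtered: np.ndarray, config: TissueConfig | None = None) -> np.ndarray:
    """Initial tissue/background split of the filtered darkest image.

    The threshold is ``percentile(filtered, init_centile) - init_offset``;
    pixels strictly below it are tissue (tissue is darker than glass in
    transmitted light).
    """
    config = config or TissueConfig()
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size == 0:
        raise DataError("cannot threshold an empty raster")
    threshold = np.percentile(filtered, config.init_centile) - config.init_offset
    logger.info("initial tissue threshold: %.2f", threshold)
    return filtered < threshold


def refine_background(
    filtered: np.ndarray, mask: np.ndarray, config: TissueConfig | None = None
) -> np.ndarray:
    """Reclassify bright tissue pixels using the background's percentile.

    The refinement threshold is the ``bg_centile`` percentile of the
    filtered values over the current background, minus ``bg_offset``;
    tissue strictly above it becomes background. With no background
    pixels the mask is returned unchanged (with a warning).
    """
    config = config or TissueConfig()
    filtered = np.asarray(filtered, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    background = ~mask
    if not background.any():
        logger.warning("refine_background: no background pixels; mask unchanged")
        return mask
    threshold = np.percentile(filtered[background], config.bg_centile) - config.bg_offset
    logger.info("background refinement threshold: %.2f", threshold)
    return mask & ~(filtered > threshold)


def _drop_small_components(mask: np.ndarray, min_px: float, connectivity: int) -> np.ndarray:
    """Set connected components with strictly fewer than min_px pixels to False."""
    labels = measure.label(mask, connectivity=connectivity)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_px)
    small = small[small > 0]
    if small.size:
        mask = mask & ~np.isin(labels, small)
    return mask


def clean_mask(
    mask: np.ndarray, pixel_size_um: float, config: TissueConfig | None = None
) -> np.ndarray:
    """Area-based cleanup of the tissue mask.

    First, connected components (8-connected by default) of tissue and of
    background with area under ``min_area_um2`` are flipped to the
    surrounding class (tissue islands first, then background islands);
    second, tissue components under ``min_tissue_fraction`` of the total
    tissue area are removed.
    """
    config = config or TissueConfig()
    mask = np.asarray(mask, dtype=bool)
    px_area = pixel_size_um**2
    min_px = config.min_area_um2 / px_area

    cleaned = _drop_small_components(mask, min_px, config.connectivity)
    cleaned = ~_drop_small_components(~cleaned, min_px, config.connectivity)

    labels = measure.label(cleaned, connectivity=config.connectivity)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())[1:]
        total = sizes.sum()
        drop = np.flatnonzero(sizes < config.min_tissue_fraction * total) + 1
        if drop.size:
            cleaned = cleaned & ~np.isin(labels, drop)
    return cleaned


def segment_tissue(
    slide: Slide, config: TissueConfig | None = None
) -> np.ndarray:
    """Full tissue-identification stage on one slide.

    Runs darkest channel -> mean filter -> percentile thresholding ->
    background refinement -> area cleanup. When ``config.downsample`` > 1
    the stage operates on a block-mean downsampled darkest image (the
    segmentation is defined at a coarser magnification than stain
    detection) and the mask is upsampled back by nearest neighbour.
    """
    config = config or TissueConfig()
    dc = darkest_channel(slide)
    f = config.downsample
    if f > 1:
        pad_r = (-dc.shape[0]) % f
        pad_c = (-dc.shape[1]) % f
        dc_pad = np.pad(dc, ((0, pad_r), (0, pad_c)), mode="reflect")
        small = dc_pad.reshape(
            dc_pad.shape[0] // f, f, dc_pad.shape[1] // f, f
        ).mean(axis=(1, 3))
        pixel_size = slide.pixel_size_um * f
    else:
        small = dc
        pixel_size = slide.pixel_size_um

    filtered = mean_filter(small, config.filter_window_px)
    mask = initial_tissue_mask(filtered, config)
    mask = refine_background(filtered, mask, config)
    mask = clean_mask(mask, pixel_size, config)

    if f > 1:
        mask = np.repeat(np.repeat(mask, f, axis=0), f, axis=1)
        mask = mask[: dc.shape[0], : dc.shape[1]]
    return mask


def select_rois(mask: np.ndarray, n_rois: int = 4) -> list[np.ndarray]:
    """Split the tissue bounding box into a grid of regions of interest.

    Automates the manual selection of ``n_rois`` regions: the tissue
    bounding box is tiled on a near-square grid and each tile is
    intersected with the tissue mask. Empty tiles are dropped with a
    warning, so fewer than ``n_rois`` masks may be returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("cannot select ROIs: tissue mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    n_rows = int(np.floor(np.sqrt(n_rois)))
    n_cols = int(np.ceil(n_rois / n_rows))
    r_edges = np.linspace(r0, r1, n_rows + 1).round().astype(int)
    c_edges = np.linspace(c0, c1, n_cols + 1).round().astype(int)

    rois: list[np.ndarray] = []
    for i in range(n_rows):
        for j in range(n_cols):
            if len(rois) == n_rois:
                break
            tile = np.zeros_like(mask)
            tile[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]] = True
            roi = tile & mask
            if roi.any():
                rois.append(roi)
    if len(rois) < n_rois:
        logger.warning("only %d of %d requested ROIs contain tissue", len(rois), n_rois)
    return rois


def rois_from_labels(label_raster: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """User-supplied ROIs as a label raster, intersected with tissue."""
    label_raster = np.asarray(label_raster)
    mask = np.asarray(mask, dtype=bool)
    if label_raster.shape != mask.shape:
        raise DataError("ROI label raster shape does not match the tissue mask")
    rois = []
    for lab in np.unique(label_raster):
        if lab == 0:
            continue
        roi = (label_raster == lab) & mask
        if roi.any():
            rois.append(roi)
        else:
            logger.warning("ROI label %s contains no tissue; dropped", lab)
    return rois
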