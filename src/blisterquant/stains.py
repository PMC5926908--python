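"""Hue-saturation-density stain separation for DAB / hematoxylin slides.

Transmitted-light stain quantification works in optical density, where
Beer-Lambert absorbances of co-localized stains add. The HSD transform
splits per-pixel density from chromatic information:

    d_ch = -ln((v_ch + 1) / (i0 + 1))        per channel
    D    = mean(d_R, d_G, d_B)               overall density (AU)
    cx   = d_R / D - 1
    cy   = (d_G - d_B) / (sqrt(3) * D)

Achromatic pixels (equal channels) sit at the chromatic origin. Each
stain's extinction vector maps to a fixed point in the (cx, cy) plane,
independent of amount; a pixel's density is attributed to a stain by
angular proximity of its hue to that reference point. From the brown
(DAB) and blue (hematoxylin) rasters the stage derives the two images
the cell-quantification stage consumes: ``brown+ve`` (brown minus blue)
and normalized blue (difference of 3 px and 101 px mean filters,
floored at 0.05 AU), which flattens diffuse background counterstain and
enhances the peaks that are nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import StainConfig, hue_angle, stain_chroma
from .tissue import Slide, mean_filter

#: below this overall density a pixel is treated as achromatic
ACHROMATIC_EPS = 1e-6


@dataclass(frozen=True)
class HSDImage:
    """Per-pixel overall optical density and chromatic coordinates."""

    density: np.ndarray
    cx: np.ndarray
    cy: np.ndarray


def rgb_to_hsd(slide: Slide, i0: int | None = None) -> HSDImage:
    """Transform an 8-bit RGB slide to hue-saturation-density space.

    The +1 regularization keeps the log defined at pixel value 0; a
    pixel at the incident intensity ``i0`` has exactly zero density.
    Pixels with density below ``ACHROMATIC_EPS`` get cx = cy = 0.
    """
    if i0 is None:
        i0 = StainConfig().i0
    v = slide.rgb.astype(float)
    d = -np.log((v + 1.0) / (i0 + 1.0))
    density = d.mean(axis=2)
    chromatic = density > ACHROMATIC_EPS
    safe = np.where(chromatic, density, 1.0)
    cx = np.where(chromatic, d[..., 0] / safe - 1.0, 0.0)
    cy = np.where(chromatic, (d[..., 1] - d[..., 2]) / (np.sqrt(3.0) * safe), 0.0)
    return HSDImage(density=density, cx=cx, cy=cy)


def hue_weight(
    cx: np.ndarray,
    cy: np.ndarray,
    reference_hue: float,
    angle_full_deg: float,
    angle_zero_deg: float,
) -> np.ndarray:
    """Trapezoidal angular-proximity weight in [0, 1].

    Weight 1 within ``angle_full_deg`` of the reference hue, falling
    linearly to 0 at ``angle_zero_deg``. Achromatic pixels (cx = cy = 0)
    have no hue and get weight 0.
    """
    theta = np.arctan2(cy, cx)
    delta = np.abs(np.angle(np.exp(1j * (theta - reference_hue))))
    delta_deg = np.degrees(delta)
    w = np.clip(
        (angle_zero_deg - delta_deg) / (angle_zero_deg - angle_full_deg), 0.0, 1.0
    )
    achromatic = (cx == 0.0) & (cy == 0.0)
    return np.where(achromatic, 0.0, w)


def stain_intensity(
    hsd: HSDImage, reference_hue: float, config: StainConfig | None = None
) -> np.ndarray:
    """Per-pixel stain intensity (AU) for one colour of interest.

    Intensity is the overall density D multiplied by the angular
    proximity weight of the pixel's hue to ``reference_hue``: D at an
    exact hue match, 0 beyond the configured half-angle.
    """
    if not np.isfinite(reference_hue):
        raise ValueError("reference hue must be finite")
    config = config or StainConfig()
    w = hue_weight(hsd.cx, hsd.cy, reference_hue, config.angle_full_deg, config.angle_zero_deg)
    return hsd.density * w


def brown_positive(brown: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Brown minus blue intensity per pixel (``brown+ve``).

    Positive where brown stain prevails; may be negative, downstream
    rules apply strict > thresholds.
    """
    brown = np.asarray(brown, dtype=float)
    blue = np.asarray(blue, dtype=float)
    if brown.shape != blue.shape:
        raise ValueError("brown and blue rasters must have the same shape")
    return brown - blue


def normalized_blue(blue: np.ndarray, config: StainConfig | None = None) -> np.ndarray:
    """Background-subtracted blue raster that enhances nuclear peaks.

    Difference of a small (3 px) and a large (101 px) mean filter of the
    blue raster, kept only where strictly greater than the configured
    floor (0.05 AU), zero elsewhere.
    """
    config = config or StainConfig()
    blue = np.asarray(blue, dtype=float)
    n = mean_filter(blue, config.blue_small_window) - mean_filter(
        blue, config.blue_large_window
    )
    return np.where(n > config.blue_floor, n, 0.0)


def stain_rasters(
    slide: Slide, config: StainConfig | None = None
) -> dict[str, np.ndarray]:
    """Run the full stain-detection stage on one slide.

    Returns the ``brown``, ``blue``, ``brown_positive`` and
    ``normalized_blue`` rasters (all AU).
    """
    config = config or StainConfig()
    hsd = rgb_to_hsd(slide, config.i0)
    hema_hue = hue_angle(*stain_chroma(np.asarray(config.extinction_hema)))
    dab_hue = hue_angle(*stain_chroma(np.asarray(config.extinction_dab)))
    blue = stain_intensity(hsd, hema_hue, config)
    brown = stain_intensity(hsd, dab_hue, config)
    return {
        "brown": brown,
        "blue": blue,
        "brown_positive": brown_positive(brown, blue),
        "normalized_blue": normalized_blue(blue, config),
    }
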