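"""Reading and writing slides, masks and label images.

Slides travel as 8-bit RGB TIFF/PNG with the physical pixel size stored
both in the TIFF resolution tags and in a sidecar YAML
(``<image>.yaml`` with a ``pixel_size_um`` field); masks as 0/255
single-channel PNG/TIFF; label images as 16-bit TIFF.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .tissue import DataError, Slide


def sidecar_path(image_path: str | Path) -> Path:
    return Path(str(image_path) + ".yaml")


def write_slide(path: str | Path, slide: Slide) -> None:
    """Write a slide as 8-bit RGB TIFF (or PNG) plus a sidecar YAML."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        # resolution tags are pixels per centimeter
        ppcm = 10_000.0 / slide.pixel_size_um
        tifffile.imwrite(
            path,
            slide.rgb,
            resolution=(ppcm, ppcm),
            resolutionunit="CENTIMETER",
        )
    else:
        iio.imwrite(path, slide.rgb)
    sidecar_path(path).write_text(
        yaml.safe_dump({"pixel_size_um": float(slide.pixel_size_um)})
    )


def read_slide(path: str | Path) -> Slide:
    """Read a slide; the pixel size comes from the sidecar or TIFF tags.

    A missing pixel size is a hard error naming the sidecar field.
    """
    path = Path(path)
    rgb = np.asarray(iio.imread(path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    pixel_size = None
    sc = sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
        pixel_size = meta.get("pixel_size_um")
    if pixel_size is None and path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None and unit is not None:
                num, den = xres.value
                if num > 0:
                    per_px = den / num  # unit per pixel
                    if unit.value == 3:  # centimeter
                        pixel_size = per_px * 10_000.0
                    elif unit.value == 2:  # inch
                        pixel_size = per_px * 25_400.0
    if pixel_size is None:
        raise DataError(
            f"no pixel size for {path}: provide 'pixel_size_um' in the sidecar "
            f"file {sc.name} or TIFF resolution tags"
        )
    return Slide(rgb=rgb.astype(np.uint8), pixel_size_um=float(pixel_size))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 single-channel image."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label raster as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise DataError("label image exceeds 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))).astype(np.int32)
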