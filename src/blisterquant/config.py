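"""Configuration objects for every pipeline stage.

All numeric thresholds used anywhere in the pipelines live in these
dataclasses, with package-wide defaults shipped in ``defaults.yaml``.
Configs can be loaded from a user YAML file that overrides any subset of
fields; whatever values were actually used are snapshotted into the run
manifest so no threshold is hidden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Invalid configuration value (maps to exit code 1 in the CLI)."""


def _load_defaults() -> dict[str, Any]:
    text = resources.files("blisterquant").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = _load_defaults()


def stain_chroma(extinction: np.ndarray) -> tuple[float, float]:
    """Chromatic (cx, cy) coordinates of a pure stain.

    A pure stain with per-channel absorbance proportional to its extinction
    vector has amount-independent chromatic coordinates; these serve as the
    reference hue for that stain.
    """
    e = np.asarray(extinction, dtype=float)
    m = e.mean()
    if m <= 0:
        raise ConfigError("extinction vector must have positive mean")
    cx = e[0] / m - 1.0
    cy = (e[1] - e[2]) / (np.sqrt(3.0) * m)
    return float(cx), float(cy)


def hue_angle(cx: float, cy: float) -> float:
    """Hue angle (radians) of chromatic coordinates."""
    return float(np.arctan2(cy, cx))


@dataclass(frozen=True)
class TissueConfig:
    """Parameters of tissue/background segmentation.

    The darkest-channel composite is mean-filtered, thresholded at
    ``init_centile`` minus ``init_offset`` (tissue is the darker side),
    refined against the background's ``bg_centile`` minus ``bg_offset``,
    and cleaned by the 50 um^2 / 1%-of-tissue area rules.
    """

    filter_window_px: int = _DEFAULTS["tissue"]["filter_window_px"]
    init_centile: float = _DEFAULTS["tissue"]["init_centile"]
    init_offset: float = _DEFAULTS["tissue"]["init_offset"]
    bg_centile: float = _DEFAULTS["tissue"]["bg_centile"]
    bg_offset: float = _DEFAULTS["tissue"]["bg_offset"]
    min_area_um2: float = _DEFAULTS["tissue"]["min_area_um2"]
    min_tissue_fraction: float = _DEFAULTS["tissue"]["min_tissue_fraction"]
    downsample: int = _DEFAULTS["tissue"]["downsample"]
    connectivity: int = _DEFAULTS["tissue"]["connectivity"]

    def __post_init__(self) -> None:
        if self.filter_window_px < 1 or self.filter_window_px % 2 == 0:
            raise ConfigError("filter_window_px must be odd and >= 1")
        for name in ("init_centile", "bg_centile"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ConfigError(f"{name} must be in (0, 100)")
        if self.init_offset < 0 or self.bg_offset < 0:
            raise ConfigError("offsets must be >= 0")
        if not 0.0 < self.min_tissue_fraction < 1.0:
            raise ConfigError("min_tissue_fraction must be in (0, 1)")
        if self.downsample < 1:
            raise ConfigError("downsample must be >= 1")
        if self.connectivity not in (1, 2):
            raise ConfigError("connectivity must be 1 or 2")


@dataclass(frozen=True)
class StainConfig:
    """Parameters of the HSD stain-separation stage.

    ``extinction_hema`` / ``extinction_dab`` define the reference hues;
    pixel density is attributed to a stain with a trapezoidal angular
    weight: 1 within ``angle_full_deg`` of the reference hue, falling
    linearly to 0 at ``angle_zero_deg``.
    """

    extinction_hema: tuple[float, float, float] = tuple(
        _DEFAULTS["stain_vectors"]["hematoxylin"]
    )
    extinction_dab: tuple[float, float, float] = tuple(_DEFAULTS["stain_vectors"]["dab"])
    blue_small_window: int = _DEFAULTS["stains"]["blue_small_window"]
    blue_large_window: int = _DEFAULTS["stains"]["blue_large_window"]
    blue_floor: float = _DEFAULTS["stains"]["blue_floor"]
    i0: int = _DEFAULTS["stains"]["i0"]
    angle_full_deg: float = _DEFAULTS["stains"]["angle_full_deg"]
    angle_zero_deg: float = _DEFAULTS["stains"]["angle_zero_deg"]

    def __post_init__(self) -> None:
        for name in ("blue_small_window", "blue_large_window"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ConfigError(f"{name} must be odd and >= 1")
        if self.blue_small_window >= self.blue_large_window:
            raise ConfigError("blue_small_window must be < blue_large_window")
        if self.blue_floor < 0:
            raise ConfigError("blue_floor must be >= 0")
        if not 0 < self.angle_full_deg < self.angle_zero_deg:
            raise ConfigError("need 0 < angle_full_deg < angle_zero_deg")

    @property
    def hema_hue(self) -> float:
        return hue_angle(*stain_chroma(np.asarray(self.extinction_hema)))

    @property
    def dab_hue(self) -> float:
        return hue_angle(*stain_chroma(np.asarray(self.extinction_dab)))


@dataclass(frozen=True)
class CellConfig:
    """Nucleus detection, cell-body growth and DAB positivity rules."""

    nb_threshold: float = _DEFAULTS["cells"]["nb_threshold"]
    min_nucleus_area_um2: float = _DEFAULTS["cells"]["min_nucleus_area_um2"]
    max_nucleus_area_um2: float = _DEFAULTS["cells"]["max_nucleus_area_um2"]
    body_depth_px: int = _DEFAULTS["cells"]["body_depth_px"]
    ref_pixel_size_um: float = _DEFAULTS["cells"]["ref_pixel_size_um"]
    dab_pixel_threshold: float = _DEFAULTS["cells"]["dab_pixel_threshold"]
    body_positive_fraction: float = _DEFAULTS["cells"]["body_positive_fraction"]
    nucleus_positive_fraction: float = _DEFAULTS["cells"]["nucleus_positive_fraction"]
    split_h: float = _DEFAULTS["cells"]["split_h"]

    def __post_init__(self) -> None:
        if not 0 < self.body_positive_fraction < 1:
            raise ConfigError("body_positive_fraction must be in (0, 1)")
        if not 0 < self.nucleus_positive_fraction < 1:
            raise ConfigError("nucleus_positive_fraction must be in (0, 1)")
        if self.min_nucleus_area_um2 >= self.max_nucleus_area_um2:
            raise ConfigError("min_nucleus_area_um2 must be < max_nucleus_area_um2")
        if self.body_depth_px < 0:
            raise ConfigError("body_depth_px must be >= 0")

    def body_depth_for(self, pixel_size_um: float) -> int:
        """Body depth in pixels at a given pixel size.

        The depth is defined in physical units (7 px at 0.45 um/px, about
        3.15 um) and rescaled to the actual pixel size.
        """
        return int(round(self.body_depth_px * self.ref_pixel_size_um / pixel_size_um))


@dataclass(frozen=True)
class MediatorConfig:
    """Identification tolerances and statistics options for LM profiling."""

    rt_tolerance_min: float = _DEFAULTS["mediators"]["rt_tolerance_min"]
    mz_tolerance: float = _DEFAULTS["mediators"]["mz_tolerance"]
    min_ions: int = _DEFAULTS["mediators"]["min_ions"]
    plsda_scaling: str = _DEFAULTS["mediators"]["plsda_scaling"]
    posthoc_correction: str = _DEFAULTS["mediators"]["posthoc_correction"]

    def __post_init__(self) -> None:
        if self.rt_tolerance_min <= 0 or self.mz_tolerance <= 0:
            raise ConfigError("tolerances must be > 0")
        if self.min_ions < 1:
            raise ConfigError("min_ions must be >= 1")
        if self.plsda_scaling not in ("auto", "pareto", "none"):
            raise ConfigError("plsda_scaling must be auto|pareto|none")


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all stage configs."""

    tissue: TissueConfig = field(default_factory=TissueConfig)
    stains: StainConfig = field(default_factory=StainConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    mediators: MediatorConfig = field(default_factory=MediatorConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, optionally overridden by a YAML file.

    The YAML file may contain any subset of the ``tissue``, ``stains``,
    ``cells`` and ``mediators`` sections; unknown keys raise
    :class:`ConfigError`.
    """
    overrides: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    sections = {
        "tissue": TissueConfig,
        "stains": StainConfig,
        "cells": CellConfig,
        "mediators": MediatorConfig,
    }
    kwargs: dict[str, Any] = {}
    for key, cls in sections.items():
        sub = overrides.pop(key, {}) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - fields
        if unknown:
            raise ConfigError(f"unknown keys in '{key}' config: {sorted(unknown)}")
        if "extinction_hema" in sub:
            sub["extinction_hema"] = tuple(sub["extinction_hema"])
        if "extinction_dab" in sub:
            sub["extinction_dab"] = tuple(sub["extinction_dab"])
        kwargs[key] = cls(**sub)
    overrides.pop("stain_vectors", None)  # top-level alias handled above
    if overrides:
        raise ConfigError(f"unknown config sections: {sorted(overrides)}")
    return PipelineConfig(**kwargs)
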