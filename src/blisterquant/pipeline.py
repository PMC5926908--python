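"""Stage composition, run manifests and artifact writing.

``run_ihc_pipeline`` chains tissue identification, stain detection and
cell quantification on one slide and writes masks, the cell table, the
density report and a manifest. ``run_lm_pipeline`` chains feature
identification/quantification (when features are supplied), PLS-DA and
per-mediator temporal tests on an exudate table. Manifests snapshot the
full configuration, input digests, seed and package versions so a rerun
with an identical manifest reproduces deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cells import (
    DensityReport,
    cells_to_frame,
    classify_cells,
    density_report,
    detect_nuclei,
    grow_cell_bodies,
)
from .config import PipelineConfig
from .mediators import (
    fit_calibration,
    identify_mediator,
    pivot_exudate,
    plsda,
    quantify,
    temporal_test,
    StandardEntry,
    MediatorFeature,
)
from .slide_io import read_slide, write_labels, write_mask
from .stains import stain_rasters
from .tissue import DataError, Slide, rois_from_labels, segment_tissue, select_rois

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    stage: str
    seed: int | None
    config: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    versions: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _versions() -> dict[str, str]:
    import scipy
    import skimage

    return {
        "blisterquant": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }


def run_ihc_pipeline(
    image: str | Path | Slide,
    config: PipelineConfig | None = None,
    roi_labels: np.ndarray | None = None,
    n_rois: int = 4,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Quantify DAB-positive cells on one slide.

    Returns a dict with the tissue mask, ROIs, stain rasters, label
    images, cell records and the :class:`DensityReport`; when ``outdir``
    is given, writes masks, label images, the cell table, the density
    report (CSV + JSON) and the run manifest there.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(stage="ihc", seed=None, config=config.to_dict(), versions=_versions())
    t0 = time.perf_counter()
    if isinstance(image, Slide):
        slide = image
    else:
        slide = read_slide(image)
        manifest.inputs[str(image)] = file_digest(image)

    tissue = segment_tissue(slide, config.tissue)
    manifest.timings_s["tissue"] = time.perf_counter() - t0

    empty = not tissue.any()
    if empty:
        logger.warning("no tissue detected; reporting an empty result")
        rois: list[np.ndarray] = []
        rasters = {}
        nuclei = np.zeros(slide.rgb.shape[:2], dtype=np.int32)
        bodies = np.zeros_like(nuclei)
        cells = []
        report = DensityReport([], [], [], 0.0)
    else:
        t1 = time.perf_counter()
        if roi_labels is not None:
            rois = rois_from_labels(roi_labels, tissue)
        else:
            rois = select_rois(tissue, n_rois=n_rois)
        rasters = stain_rasters(slide, config.stains)
        manifest.timings_s["stains"] = time.perf_counter() - t1
        t2 = time.perf_counter()
        nuclei = detect_nuclei(
            rasters["normalized_blue"], tissue, config.cells, slide.pixel_size_um
        )
        bodies = grow_cell_bodies(nuclei, tissue, config.cells, slide.pixel_size_um)
        cells = classify_cells(nuclei, bodies, rasters["brown_positive"], config.cells)
        report = density_report(cells, rois, tissue, slide.pixel_size_um)
        manifest.timings_s["cells"] = time.perf_counter() - t2

    result = {
        "slide": slide,
        "tissue_mask": tissue,
        "rois": rois,
        "rasters": rasters,
        "nucleus_labels": nuclei,
        "body_labels": bodies,
        "cells": cells,
        "report": report,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mask(outdir / "tissue_mask.png", tissue)
        write_labels(outdir / "nucleus_labels.tif", nuclei)
        write_labels(outdir / "body_labels.tif", bodies)
        cells_to_frame(cells).to_csv(outdir / "cells.csv", index=False)
        report.to_frame().to_csv(outdir / "density.csv", index=False)
        (outdir / "density.json").write_text(
            json.dumps(
                {
                    "mean_density_per_um2": report.mean_density,
                    "roi_densities": report.roi_densities,
                    "roi_positive_counts": report.roi_positive_counts,
                    "roi_tissue_areas_um2": report.roi_tissue_areas_um2,
                },
                indent=2,
            )
        )
        manifest.outputs = [
            "tissue_mask.png",
            "nucleus_labels.tif",
            "body_labels.tif",
            "cells.csv",
            "density.csv",
            "density.json",
        ]
        manifest.write(outdir / "manifest.json")
    return result


def load_standard_library(path: str | Path) -> list[StandardEntry]:
    """Standard library from CSV (ions separated by ';') or JSON."""
    path = Path(path)
    entries: list[StandardEntry] = []
    if path.suffix.lower() == ".json":
        for row in json.loads(path.read_text()):
            entries.append(
                StandardEntry(
                    name=row["name"],
                    retention_time_min=float(row["retention_time_min"]),
                    mrm_parent_mz=float(row["mrm_parent_mz"]),
                    mrm_product_mz=float(row["mrm_product_mz"]),
                    diagnostic_ions=tuple(float(x) for x in row["diagnostic_ions"]),
                    istd_name=row.get("istd_name", ""),
                )
            )
    else:
        df = pd.read_csv(path)
        for _, row in df.iterrows():
            ions = tuple(float(x) for x in str(row["diagnostic_ions"]).split(";"))
            entries.append(
                StandardEntry(
                    name=row["name"],
                    retention_time_min=float(row["retention_time_min"]),
                    mrm_parent_mz=float(row["mrm_parent_mz"]),
                    mrm_product_mz=float(row["mrm_product_mz"]),
                    diagnostic_ions=ions,
                    istd_name=str(row.get("istd_name", "")),
                )
            )
    return entries


def save_standard_library(path: str | Path, library: list[StandardEntry]) -> None:
    rows = [
        {
            "name": e.name,
            "retention_time_min": e.retention_time_min,
            "mrm_parent_mz": e.mrm_parent_mz,
            "mrm_product_mz": e.mrm_product_mz,
            "diagnostic_ions": ";".join(str(i) for i in e.diagnostic_ions),
            "istd_name": e.istd_name,
        }
        for e in library
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def load_features(path: str | Path) -> list[MediatorFeature]:
    """Observed features from CSV (ions separated by ';')."""
    df = pd.read_csv(Path(path))
    required = {"retention_time_min", "ions_mz", "peak_area", "istd_peak_area"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"feature table is missing columns: {sorted(missing)}")
    return [
        MediatorFeature(
            retention_time_min=float(r["retention_time_min"]),
            ions_mz=tuple(float(x) for x in str(r["ions_mz"]).split(";")),
            peak_area=float(r["peak_area"]),
            istd_peak_area=float(r["istd_peak_area"]),
        )
        for _, r in df.iterrows()
    ]


def save_features(path: str | Path, features: list[MediatorFeature]) -> None:
    rows = [
        {
            "retention_time_min": f.retention_time_min,
            "ions_mz": ";".join(str(i) for i in f.ions_mz),
            "peak_area": f.peak_area,
            "istd_peak_area": f.istd_peak_area,
        }
        for f in features
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def run_lm_pipeline(
    table: str | Path | pd.DataFrame,
    library: list[StandardEntry] | None = None,
    features: list[MediatorFeature] | None = None,
    calibration: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    reference_time: float = 0.0,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Profile an exudate table: identification, PLS-DA, temporal tests.

    ``table`` is a long-format (donor, time_h, mediator,
    concentration_pg) table. When ``features`` and ``library`` are
    given, each feature is identified and, when ``calibration``
    (columns mediator, amount_pg, response) is also given, quantified.
    With a single time point PLS-DA is refused and temporal tests are
    skipped, with clear messages.
    """
    config = config or PipelineConfig()
    mcfg = config.mediators
    manifest = RunManifest(stage="lm", seed=None, config=config.to_dict(), versions=_versions())
    if not isinstance(table, pd.DataFrame):
        manifest.inputs[str(table)] = file_digest(table)
        table = pd.read_csv(table)
    required = {"donor", "time_h", "mediator", "concentration_pg"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"exudate table is missing columns: {sorted(missing)}")

    identifications = None
    if features is not None and library is not None:
        curves = {}
        if calibration is not None:
            for med, grp in calibration.groupby("mediator"):
                curves[med] = fit_calibration(
                    grp["amount_pg"], grp["response"], mediator=str(med)
                )
        rows = []
        for f in features:
            match = identify_mediator(
                f,
                library,
                rt_tolerance_min=mcfg.rt_tolerance_min,
                min_ions=mcfg.min_ions,
                mz_tolerance=mcfg.mz_tolerance,
            )
            amount = np.nan
            if match.identified and match.name in curves and f.istd_peak_area > 0:
                amount = quantify(f, curves[match.name])
            rows.append(
                {
                    "retention_time_min": f.retention_time_min,
                    "identified_as": match.name,
                    "ions_matched": match.ions_matched,
                    "amount_pg": amount,
                }
            )
        identifications = pd.DataFrame(rows)

    times = np.unique(table["time_h"])
    plsda_result = None
    temporal_results = []
    if times.size < 2:
        logger.warning(
            "only one time point present: PLS-DA refused and temporal tests skipped"
        )
    else:
        wide, groups = pivot_exudate(table)
        plsda_result = plsda(wide, groups, n_components=2, scaling=mcfg.plsda_scaling)
        counts = table.groupby(["mediator", "time_h"]).size()
        for med in sorted(table["mediator"].unique()):
            if counts[med].min() < 2:
                logger.warning("mediator %s has a time group with < 2 observations; skipped", med)
                continue
            temporal_results.append(
                temporal_test(
                    table,
                    med,
                    reference_time=reference_time,
                    correction=mcfg.posthoc_correction,
                )
            )

    result = {
        "table": table,
        "identifications": identifications,
        "plsda": plsda_result,
        "temporal": temporal_results,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs = []
        if identifications is not None:
            identifications.to_csv(outdir / "identifications.csv", index=False)
            outputs.append("identifications.csv")
        if plsda_result is not None:
            plsda_result.scores.assign(time_h=plsda_result.groups).to_csv(
                outdir / "plsda_scores.csv"
            )
            plsda_result.loadings.to_csv(outdir / "plsda_loadings.csv")
            pd.DataFrame(
                {
                    "component": [f"comp{i+1}" for i in range(len(plsda_result.explained_variance_x))],
                    "explained_variance_x": plsda_result.explained_variance_x,
                    "explained_variance_y": plsda_result.explained_variance_y,
                }
            ).to_csv(outdir / "plsda_variance.csv", index=False)
            pd.DataFrame(
                [
                    {
                        "group": e.group,
                        "center_1": e.center[0],
                        "center_2": e.center[1],
                        "semi_axis_1": e.semi_axes[0],
                        "semi_axis_2": e.semi_axes[1],
                        "angle_rad": e.angle_rad,
                    }
                    for e in plsda_result.ellipses
                ]
            ).to_csv(outdir / "plsda_ellipses.csv", index=False)
            outputs += [
                "plsda_scores.csv",
                "plsda_loadings.csv",
                "plsda_variance.csv",
                "plsda_ellipses.csv",
            ]
        if temporal_results:
            frames = []
            for r in temporal_results:
                df = r.comparisons.copy()
                df.insert(0, "mediator", r.mediator)
                df.insert(1, "h_statistic", r.h_statistic)
                df.insert(2, "p_omnibus", r.p_value)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "temporal_tests.csv", index=False
            )
            outputs.append("temporal_tests.csv")
        manifest.outputs = outputs
        manifest.write(outdir / "manifest.json")
    return result
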