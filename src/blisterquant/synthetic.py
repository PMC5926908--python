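"""Ground-truthed synthetic data for every pipeline stage.

Slides are rendered through a Beer-Lambert forward model: each channel
is ``I0 * exp(-(A_hema * e_hema + A_dab * e_dab))`` with additive
Gaussian noise, quantized to 8 bits after the noise. Hematoxylin-stained
elliptical nuclei sit on a faintly counterstained tissue background
inside a stain-free glass margin; DAB-positive cells carry chromogen on
a cytoplasmic ring (and optionally on the nucleus). A "merged pair"
mode plants nucleus pairs closer than the minimum spacing to exercise
the merged-nucleus splitting step.

Mediator tables emulate the temporal structure of exudate lipid-mediator
profiles over a 0/4/8/14/24 h blister time course: onset eicosanoids
(PGE2-type) peaking at 4 h, an E-series resolvin peaking at 8 h, LXA4
rising late, and MaR1 dipping at 8 h before recovering. Concentrations
are log-normal with a configurable coefficient of variation and an
expected value of baseline x temporal effect.

MS/MS feature fixtures carry truth labels that are valid by
construction: decoys either keep at most 5 diagnostic ions (filler ions
come from an m/z range no standard uses) or sit in retention-time gaps
at least 2.5 tolerances from every library entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .config import StainConfig
from .mediators import MediatorFeature, StandardEntry
from .tissue import Slide


class SlideCapacityError(RuntimeError):
    """Requested cells cannot be placed in the available tissue."""


@dataclass(frozen=True)
class OpticalModel:
    """Brightfield forward model parameters.

    ``background_intensity`` is the incident (glass) 8-bit level per
    channel; extinction vectors are per-channel absorbance coefficients;
    ``noise_sd`` is additive Gaussian noise on the 8-bit scale, applied
    before quantization.
    """

    background_intensity: tuple[int, int, int] = (255, 255, 255)
    extinction_hema: tuple[float, float, float] = StainConfig().extinction_hema
    extinction_dab: tuple[float, float, float] = StainConfig().extinction_dab
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.extinction_hema) < 0 or min(self.extinction_dab) < 0:
            raise ValueError("extinction coefficients must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SlideSpec:
    """Geometry and staining amounts of a synthetic slide.

    Nuclei are ellipses (default 3 um semi-axes, i.e. circles) placed by
    rejection sampling with a minimum centroid distance;
    ``n_merged_pairs`` of the requested cells are instead placed as
    close pairs (separation ``merged_pair_sep_um``) to create merged
    nuclei. Amounts are Beer-Lambert stain quantities (dimensionless
    multiples of the extinction vectors).
    """

    shape: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.45
    n_positive: int = 60
    n_negative: int = 40
    nucleus_radii_um: tuple[float, float] = (3.0, 3.0)
    min_centroid_dist_um: float = 9.0
    n_merged_pairs: int = 0
    merged_pair_sep_um: float = 5.4
    tissue_axes_frac: tuple[float, float] = (0.44, 0.46)
    tissue_hema: float = 0.18
    nucleus_hema: float = 0.9
    dab_amount: float = 0.8
    dab_on_nucleus: bool = False

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("cell counts must be >= 0")
        a, b = self.nucleus_radii_um
        if np.pi * a * b <= 10.0:
            raise ValueError(
                "nucleus area must exceed the 10 um^2 detection floor; "
                f"got {np.pi * a * b:.2f} um^2"
            )
        if 2 * self.n_merged_pairs > self.n_positive + self.n_negative:
            raise ValueError("more merged-pair cells than total cells")


@dataclass(frozen=True)
class PlantedCell:
    """Ground truth for one planted cell."""

    cell_id: int
    centroid_rc: tuple[float, float]
    is_dab_positive: bool


@dataclass(frozen=True)
class SlideGroundTruth:
    """Everything the generator knows about a synthetic slide.

    ``nucleus_labels`` / ``body_labels`` encode the planted pixel sets
    (bodies are pixels within the body depth of their Euclidean-nearest
    nucleus); ``hema_amounts`` / ``dab_amounts`` are the planted stain
    quantity rasters, for forward/inversion checks.
    """

    tissue_mask: np.ndarray
    nucleus_labels: np.ndarray
    body_labels: np.ndarray
    hema_amounts: np.ndarray
    dab_amounts: np.ndarray
    cells: list[PlantedCell]
    pixel_size_um: float

    @property
    def n_positive(self) -> int:
        return sum(c.is_dab_positive for c in self.cells)

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / len(self.cells) if self.cells else 0.0

    def planted_density(self, model: OpticalModel) -> np.ndarray:
        """Planted overall optical density D (AU) per pixel."""
        e_h = float(np.mean(model.extinction_hema))
        e_d = float(np.mean(model.extinction_dab))
        return self.hema_amounts * e_h + self.dab_amounts * e_d


def _ellipse_mask(shape, center_rc, radii_px, angle_rad):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center_rc[0]
    dc = cc - center_rc[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii_px[0]) ** 2 + (v / radii_px[1]) ** 2 <= 1.0


def _place_centroids(spec: SlideSpec, allowed: np.ndarray, rng: np.random.Generator):
    """Rejection-sample cell centroids; raises SlideCapacityError when stuck."""
    px = spec.pixel_size_um
    min_dist_px = spec.min_centroid_dist_um / px
    sep_px = spec.merged_pair_sep_um / px
    n_total = spec.n_positive + spec.n_negative
    rows, cols = np.nonzero(allowed)
    if rows.size == 0:
        raise SlideCapacityError("no tissue area available for cell placement")
    placed: list[tuple[float, float]] = []

    def far_enough(r, c, skip_last=0):
        ref = placed[: len(placed) - skip_last] if skip_last else placed
        return all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist_px**2 for pr, pc in ref)

    max_attempts = 2000
    n_singles = n_total - 2 * spec.n_merged_pairs
    for _ in range(spec.n_merged_pairs):
        for attempt in range(max_attempts):
            i = rng.integers(rows.size)
            r, c = float(rows[i]), float(cols[i])
            theta = rng.uniform(0, 2 * np.pi)
            r2 = r + sep_px * np.sin(theta)
            c2 = c + sep_px * np.cos(theta)
            ir2, ic2 = int(round(r2)), int(round(c2))
            inside = (
                0 <= ir2 < allowed.shape[0]
                and 0 <= ic2 < allowed.shape[1]
                and allowed[ir2, ic2]
            )
            if inside and far_enough(r, c) and far_enough(r2, c2):
                placed.extend([(r, c), (r2, c2)])
                break
        else:
            raise SlideCapacityError("could not place merged pair; spec overcrowded")
    for _ in range(n_singles):
        for attempt in range(max_attempts):
            i = rng.integers(rows.size)
            r, c = float(rows[i]), float(cols[i])
            if far_enough(r, c):
                placed.append((r, c))
                break
        else:
            raise SlideCapacityError("could not place cell; spec overcrowded")
    return placed


def _body_labels_from_nuclei(
    nucleus_labels: np.ndarray, tissue: np.ndarray, depth_px: int
) -> np.ndarray:
    """Planted body pixels: within depth of the nearest nucleus, in tissue."""
    bodies = np.zeros_like(nucleus_labels)
    nuclei = nucleus_labels > 0
    if not nuclei.any() or depth_px == 0:
        return bodies
    dist = ndi.distance_transform_edt(~nuclei)
    candidates = (dist <= depth_px) & ~nuclei & tissue
    coords = np.column_stack(np.nonzero(nuclei))
    labels_at = nucleus_labels[nuclei]
    tree = cKDTree(coords)
    pts = np.column_stack(np.nonzero(candidates))
    k = min(8, coords.shape[0])
    d, idx = tree.query(pts, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    ties = d <= d[:, :1] + 1e-9
    cand = np.where(ties, labels_at[idx].astype(np.int64), np.iinfo(np.int64).max)
    bodies[pts[:, 0], pts[:, 1]] = cand.min(axis=1).astype(bodies.dtype)
    return bodies


def generate_ihc_slide(
    spec: SlideSpec | None = None,
    model: OpticalModel | None = None,
    seed: int = 0,
    body_depth_px: int = 7,
) -> tuple[Slide, SlideGroundTruth]:
    """Render a ground-truthed synthetic DAB/hematoxylin slide.

    Returns the 8-bit RGB slide and the full ground truth (tissue mask,
    nucleus/body label rasters, stain amount rasters, per-cell
    positivity). Deterministic for a fixed spec and seed.
    """
    spec = spec or SlideSpec()
    model = model or OpticalModel()
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    px = spec.pixel_size_um
    radii_px = (spec.nucleus_radii_um[0] / px, spec.nucleus_radii_um[1] / px)

    rr, cc = np.ogrid[:h, :w]
    tissue = (
        ((rr - h / 2) / (spec.tissue_axes_frac[0] * h)) ** 2
        + ((cc - w / 2) / (spec.tissue_axes_frac[1] * w)) ** 2
    ) <= 1.0

    margin = int(np.ceil(max(radii_px) + body_depth_px + 2))
    allowed = ndi.binary_erosion(tissue, iterations=margin)
    centroids = _place_centroids(spec, allowed, rng)

    n_total = spec.n_positive + spec.n_negative
    flags = np.array([True] * spec.n_positive + [False] * spec.n_negative)
    rng.shuffle(flags)

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cells: list[PlantedCell] = []
    for i, (r, c) in enumerate(centroids, start=1):
        angle = rng.uniform(0, np.pi) if radii_px[0] != radii_px[1] else 0.0
        mask = _ellipse_mask((h, w), (r, c), radii_px, angle)
        nucleus_labels[mask] = i
        cells.append(PlantedCell(cell_id=i, centroid_rc=(r, c), is_dab_positive=bool(flags[i - 1])))

    body_labels = _body_labels_from_nuclei(nucleus_labels, tissue, body_depth_px)

    hema = np.where(tissue, spec.tissue_hema, 0.0)
    hema = np.where(nucleus_labels > 0, spec.tissue_hema + spec.nucleus_hema, hema)
    dab = np.zeros((h, w), dtype=float)
    positive_ids = [c.cell_id for c in cells if c.is_dab_positive]
    if positive_ids:
        ring = np.isin(body_labels, positive_ids)
        dab[ring] = spec.dab_amount
        if spec.dab_on_nucleus:
            dab[np.isin(nucleus_labels, positive_ids)] = spec.dab_amount

    rgb = np.empty((h, w, 3), dtype=np.uint8)
    for ch in range(3):
        i0 = model.background_intensity[ch]
        absorbance = hema * model.extinction_hema[ch] + dab * model.extinction_dab[ch]
        intensity = i0 * np.exp(-absorbance)
        if model.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, model.noise_sd, size=intensity.shape)
        rgb[..., ch] = np.clip(np.round(intensity), 0, 255).astype(np.uint8)

    truth = SlideGroundTruth(
        tissue_mask=tissue,
        nucleus_labels=nucleus_labels,
        body_labels=body_labels,
        hema_amounts=hema,
        dab_amounts=dab,
        cells=cells,
        pixel_size_um=px,
    )
    return Slide(rgb=rgb, pixel_size_um=px), truth


def match_centroids(
    detected: np.ndarray, planted: np.ndarray, max_dist_px: float
) -> tuple[int, int, int]:
    """Optimal one-to-one centroid matching (Hungarian assignment).

    Returns (true positives, false positives, false negatives); a pair
    counts as matched only within ``max_dist_px``.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    planted = np.atleast_2d(np.asarray(planted, dtype=float))
    if detected.size == 0 or planted.size == 0:
        return 0, len(detected) if detected.size else 0, len(planted) if planted.size else 0
    cost = np.linalg.norm(detected[:, None, :] - planted[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    tp = int(np.sum(cost[rows, cols] <= max_dist_px))
    return tp, detected.shape[0] - tp, planted.shape[0] - tp


def centroid_f1(detected, planted, max_dist_px: float) -> float:
    """F1 score of detected vs planted centroids."""
    tp, fp, fn = match_centroids(detected, planted, max_dist_px)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


# --------------------------------------------------------------------------
# Mediator time-course tables
# --------------------------------------------------------------------------

DEFAULT_MEDIATORS = (
    "PGE2", "PGD2", "PGF2a", "TxB2",
    "LTB4", "20-OH-LTB4", "20-COOH-LTB4",
    "LXA4", "LXB4", "15-epi-LXA4",
    "RvE1", "RvE2", "RvE3",
    "RvD1", "RvD2", "RvD5",
    "PD1", "PDX", "MaR1", "MaR2",
)

#: directional temporal profiles over (0, 4, 8, 14, 24) h: onset
#: eicosanoids and LXB4 peak at 4 h, RvE3 at 8 h, LXA4 rises late,
#: MaR1 dips at 8 h then recovers; unlisted mediators are flat.
DEFAULT_PROFILES: dict[str, tuple[float, ...]] = {
    "PGE2": (1.0, 3.0, 1.5, 1.0, 1.0),
    "PGF2a": (1.0, 3.0, 1.5, 1.0, 1.0),
    "TxB2": (1.0, 2.5, 1.5, 1.0, 1.0),
    "LTB4": (1.0, 2.5, 1.5, 1.0, 1.0),
    "20-OH-LTB4": (1.0, 3.0, 1.5, 1.0, 1.0),
    "20-COOH-LTB4": (1.0, 2.5, 1.5, 1.0, 1.0),
    "LXB4": (1.0, 2.0, 1.2, 1.0, 1.0),
    "RvE3": (1.0, 1.5, 3.0, 1.5, 1.0),
    "LXA4": (1.0, 1.0, 1.3, 1.8, 2.2),
    "MaR1": (1.0, 0.7, 0.4, 0.8, 1.2),
}


@dataclass(frozen=True)
class MediatorSimSpec:
    """Simulation spec for mediator concentration tables.

    Concentrations are log-normal with expected value
    ``baseline_pg[m] * temporal_effect[m][t]`` and coefficient of
    variation ``noise_cv``; a fixed seed reproduces the table exactly.
    """

    mediators: tuple[str, ...] = DEFAULT_MEDIATORS
    time_points_h: tuple[float, ...] = (0.0, 4.0, 8.0, 14.0, 24.0)
    donors_per_time: int = 7
    baseline_pg: float | dict[str, float] = 10.0
    temporal_effect: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    noise_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donors_per_time < 1:
            raise ValueError("donors_per_time must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        baselines = (
            self.baseline_pg.values()
            if isinstance(self.baseline_pg, dict)
            else [self.baseline_pg]
        )
        if any(b < 0 for b in baselines):
            raise ValueError("baseline_pg must be >= 0")
        for name, prof in self.temporal_effect.items():
            if len(prof) != len(self.time_points_h):
                raise ValueError(
                    f"profile for {name} has {len(prof)} values, "
                    f"expected {len(self.time_points_h)}"
                )

    def baseline_for(self, mediator: str) -> float:
        if isinstance(self.baseline_pg, dict):
            return self.baseline_pg.get(mediator, 10.0)
        return self.baseline_pg

    def effect_for(self, mediator: str) -> tuple[float, ...]:
        return self.temporal_effect.get(
            mediator, tuple(1.0 for _ in self.time_points_h)
        )


def generate_mediator_table(spec: MediatorSimSpec | None = None) -> pd.DataFrame:
    """Long-format exudate table (donor, time_h, mediator, concentration_pg)."""
    spec = spec or MediatorSimSpec()
    rng = np.random.default_rng(spec.seed)
    cv = spec.noise_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    rows = []
    donor_idx = 0
    for ti, t in enumerate(spec.time_points_h):
        for _ in range(spec.donors_per_time):
            donor = f"D{donor_idx:03d}"
            donor_idx += 1
            for m in spec.mediators:
                mean = spec.baseline_for(m) * spec.effect_for(m)[ti]
                if sigma > 0:
                    conc = mean * np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                else:
                    conc = mean
                rows.append((donor, t, m, conc))
    return pd.DataFrame(rows, columns=["donor", "time_h", "mediator", "concentration_pg"])


# --------------------------------------------------------------------------
# MS/MS feature fixtures
# --------------------------------------------------------------------------

_ISTD_FOR = {
    "PGE2": "d4-PGE2", "PGD2": "d4-PGE2", "PGF2a": "d4-PGE2", "TxB2": "d4-PGE2",
    "LTB4": "d4-LTB4", "20-OH-LTB4": "d4-LTB4", "20-COOH-LTB4": "d4-LTB4",
    "LXA4": "d5-LXA4", "LXB4": "d5-LXA4", "15-epi-LXA4": "d5-LXA4",
    "RvE1": "d5-LXA4", "RvE2": "d5-LXA4", "RvE3": "d5-LXA4",
    "RvD1": "d5-RvD2", "RvD2": "d5-RvD2", "RvD5": "d5-RvD2",
    "PD1": "d5-RvD2", "PDX": "d5-RvD2", "MaR1": "d5-RvD2", "MaR2": "d5-RvD2",
}

# (parent m/z, product m/z, retention time min); transitions follow
# literature-typical negative-mode MRM pairs for each mediator, retention
# times are synthetic placeholders spaced >= 0.5 min apart.
_LIBRARY_ROWS = {
    "TxB2": (369.2, 169.1, 3.8),
    "PGF2a": (353.2, 193.1, 4.4),
    "PGE2": (351.2, 271.2, 5.0),
    "PGD2": (351.2, 189.1, 5.6),
    "20-OH-LTB4": (351.2, 195.1, 6.2),
    "20-COOH-LTB4": (365.2, 195.1, 6.8),
    "LXB4": (351.2, 221.1, 7.4),
    "LXA4": (351.2, 115.1, 8.0),
    "15-epi-LXA4": (351.2, 115.1, 8.6),
    "RvE1": (349.2, 195.1, 9.2),
    "RvE2": (333.2, 253.2, 9.8),
    "RvE3": (333.2, 201.1, 10.4),
    "RvD1": (375.2, 215.1, 11.0),
    "RvD2": (375.2, 175.1, 11.6),
    "RvD5": (359.2, 199.1, 12.2),
    "PD1": (359.2, 153.1, 12.8),
    "PDX": (359.2, 153.1, 13.4),
    "MaR1": (359.2, 250.1, 14.0),
    "MaR2": (359.2, 221.1, 14.6),
    "LTB4": (335.2, 195.1, 15.2),
}

#: filler m/z grid no standard entry uses (all library ions are < 400)
_JUNK_MZ_GRID = 900.0 + 0.37 * np.arange(200)


def default_standard_library() -> list[StandardEntry]:
    """Built-in 20-mediator standard library.

    Each entry carries 7 diagnostic ions: the MRM parent and product,
    the usual neutral losses (water, CO2, water+CO2, product-water) and
    one entry-unique fragment. Ion lists are synthetic stand-ins for the
    published spectra, adequate for exercising the >= 6-ion rule.
    """
    entries = []
    for i, (name, (parent, product, rt)) in enumerate(_LIBRARY_ROWS.items()):
        ions = [
            parent,
            product,
            round(parent - 18.0, 1),
            round(parent - 44.0, 1),
            round(parent - 62.0, 1),
            round(product - 18.0, 1),
            round(100.0 + 7.3 * i, 1),
        ]
        entries.append(
            StandardEntry(
                name=name,
                retention_time_min=rt,
                mrm_parent_mz=parent,
                mrm_product_mz=product,
                diagnostic_ions=tuple(ions),
                istd_name=_ISTD_FOR[name],
            )
        )
    return entries


def generate_msms_features(
    library: list[StandardEntry],
    n_true: int,
    n_decoy: int,
    rt_jitter: float = 0.05,
    seed: int = 0,
) -> tuple[list[MediatorFeature], list[str | None]]:
    """Labelled feature fixtures for the identification rules.

    True features carry all diagnostic ions of one entry at a retention
    time within ``rt_jitter``; decoys cycle through three violation
    modes (only 5 matching ions; retention time shifted 0.25 min into a
    library gap; both). Returns the features and their truth labels
    (entry name or None).
    """
    if not library:
        raise ValueError("standard library must not be empty")
    rng = np.random.default_rng(seed)
    features: list[MediatorFeature] = []
    labels: list[str | None] = []

    def junk_ions(n):
        return list(rng.choice(_JUNK_MZ_GRID, size=n, replace=False))

    for _ in range(n_true):
        entry = library[rng.integers(len(library))]
        rt = entry.retention_time_min + rng.uniform(-rt_jitter, rt_jitter)
        ions = list(entry.diagnostic_ions) + junk_ions(2)
        rng.shuffle(ions)
        features.append(
            MediatorFeature(
                retention_time_min=float(rt),
                ions_mz=tuple(ions),
                peak_area=float(rng.uniform(1e4, 1e6)),
                istd_peak_area=float(rng.uniform(1e4, 1e5)),
            )
        )
        labels.append(entry.name)

    modes = ("few_ions", "rt_shift", "both")
    for j in range(n_decoy):
        entry = library[rng.integers(len(library))]
        mode = modes[j % 3]
        if mode in ("few_ions", "both"):
            ions = list(entry.diagnostic_ions[:5]) + junk_ions(3)
        else:
            ions = list(entry.diagnostic_ions) + junk_ions(1)
        if mode in ("rt_shift", "both"):
            rt = entry.retention_time_min + 0.25 + rng.uniform(-0.03, 0.03)
        else:
            rt = entry.retention_time_min + rng.uniform(-rt_jitter, rt_jitter)
        rng.shuffle(ions)
        features.append(
            MediatorFeature(
                retention_time_min=float(rt),
                ions_mz=tuple(ions),
                peak_area=float(rng.uniform(1e4, 1e6)),
                istd_peak_area=float(rng.uniform(1e4, 1e5)),
            )
        )
        labels.append(None)
    return features, labels
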