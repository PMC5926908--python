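"""Lipid-mediator identification, quantification and temporal statistics.

Identification follows targeted metabololipidomics practice: an observed
LC-MS/MS feature is assigned to a standard when its retention time
matches the synthetic standard within tolerance and at least six of the
standard's diagnostic MS/MS ions are present. Quantification uses
internal-standard-normalized responses against linear calibration
curves fitted on the 0.78-200 pg dilution series. Temporal structure is
profiled two ways: partial least squares discriminant analysis (NIPALS,
one-hot time-point response, 95% confidence ellipses on the
two-component score plane) and a Kruskal-Wallis omnibus test per
mediator followed by Dunn's rank-based many-to-one comparisons against
the baseline time point with multiplicity adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: calibration dilution series (pg) used for every mediator standard
CALIBRATION_AMOUNTS_PG = (0.78, 1.56, 3.12, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0)


@dataclass(frozen=True)
class StandardEntry:
    """A reference standard: retention time, MRM transition, diagnostic ions."""

    name: str
    retention_time_min: float
    mrm_parent_mz: float
    mrm_product_mz: float
    diagnostic_ions: tuple[float, ...]
    istd_name: str = ""

    def __post_init__(self) -> None:
        if len(self.diagnostic_ions) < 6:
            raise ValueError(
                f"{self.name}: standards need >= 6 diagnostic ions, "
                f"got {len(self.diagnostic_ions)}"
            )
        if not self.retention_time_min > 0:
            raise ValueError("retention time must be > 0")


@dataclass(frozen=True)
class MediatorFeature:
    """An observed LC-MS/MS feature."""

    retention_time_min: float
    ions_mz: tuple[float, ...]
    peak_area: float = 0.0
    istd_peak_area: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_area < 0 or self.istd_peak_area < 0:
            raise ValueError("peak areas must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one feature against the standard library."""

    name: str | None
    ions_matched: int
    rt_delta_min: float

    @property
    def identified(self) -> bool:
        return self.name is not None


def count_matched_ions(
    feature: MediatorFeature, entry: StandardEntry, mz_tolerance: float
) -> int:
    """Number of the entry's diagnostic ions present in the observed list."""
    obs = np.asarray(feature.ions_mz, dtype=float)
    if obs.size == 0:
        return 0
    n = 0
    for ion in entry.diagnostic_ions:
        if np.min(np.abs(obs - ion)) <= mz_tolerance:
            n += 1
    return n


def identify_mediator(
    feature: MediatorFeature,
    library: list[StandardEntry],
    rt_tolerance_min: float = 0.1,
    min_ions: int = 6,
    mz_tolerance: float = 0.01,
) -> MatchResult:
    """Assign a feature to a standard, or to none.

    A feature matches entry E iff its retention time is within
    ``rt_tolerance_min`` of E's and at least ``min_ions`` of E's
    diagnostic ions are observed within ``mz_tolerance``. Among several
    qualifying entries the one with most matched ions wins; ties go to
    the smallest retention-time difference.
    """
    if not library:
        raise ValueError("standard library must not be empty")
    best: MatchResult = MatchResult(None, 0, float("inf"))
    for entry in library:
        dt = abs(feature.retention_time_min - entry.retention_time_min)
        if dt > rt_tolerance_min:
            continue
        n = count_matched_ions(feature, entry, mz_tolerance)
        if n < min_ions:
            continue
        if n > best.ions_matched or (n == best.ions_matched and dt < best.rt_delta_min):
            best = MatchResult(entry.name, n, dt)
    return best


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration of response vs amount for one mediator."""

    mediator: str
    amounts_pg: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    r2: float


def fit_calibration(
    amounts, responses, mediator: str = ""
) -> CalibrationCurve:
    """Ordinary least-squares calibration line (response = slope*amount + b)."""
    amounts = np.asarray(amounts, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if amounts.size < 3:
        raise ValueError("calibration needs >= 3 points")
    if np.unique(amounts).size != amounts.size or np.any(amounts <= 0):
        raise ValueError("calibration amounts must be strictly positive and distinct")
    fit = stats.linregress(amounts, responses)
    return CalibrationCurve(
        mediator=mediator,
        amounts_pg=tuple(amounts),
        responses=tuple(responses),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def quantify(feature: MediatorFeature, curve: CalibrationCurve) -> float:
    """Amount (pg) of a feature from its internal-standard response.

    Response is peak area over internal-standard peak area; amounts
    below zero (response under the intercept) are floored at 0 with a
    warning.
    """
    if feature.istd_peak_area <= 0:
        raise ValueError("internal-standard peak area must be > 0")
    if curve.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    response = feature.peak_area / feature.istd_peak_area
    amount = (response - curve.intercept) / curve.slope
    if amount < 0:
        logger.warning(
            "%s: response below calibration intercept; amount floored at 0",
            curve.mediator or "feature",
        )
        return 0.0
    return float(amount)


# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEllipse:
    """95% confidence ellipse of one group on the score plane."""

    group: object
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float


@dataclass(frozen=True)
class PlsdaResult:
    """Scores, loadings and per-group confidence ellipses.

    ``loadings`` are the unit-norm X-weights of each component (the
    quantities plotted in metabolomics loading plots);
    ``explained_variance_x``/``_y`` give the fraction of predictor and
    response variance captured per component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_x: tuple[float, ...]
    explained_variance_y: tuple[float, ...]
    groups: np.ndarray
    ellipses: list[GroupEllipse] = field(default_factory=list)


def _impute_half_minimum(X: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by half the minimum observed per mediator."""
    if not X.isna().any().any():
        return X
    X = X.copy()
    for col in X.columns:
        if X[col].isna().any():
            observed = X[col].dropna()
            fill = observed.min() / 2.0 if not observed.empty else 0.0
            logger.info("imputing %d missing values of %s with %.4g",
                        X[col].isna().sum(), col, fill)
            X[col] = X[col].fillna(fill)
    return X


def plsda(
    X,
    groups,
    n_components: int = 2,
    scaling: str = "auto",
    conf_level: float = 0.95,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> PlsdaResult:
    """Partial least squares discriminant analysis (NIPALS).

    Predictors are centred and scaled (``auto`` = unit variance,
    ``pareto`` = sqrt of the standard deviation, ``none`` = centring
    only); the response is the centred one-hot group membership matrix.
    Latent variables are extracted by the iterative NIPALS algorithm
    with X-deflation. Per-group confidence ellipses on the first two
    components come from the group score covariance and the chi-square
    quantile with 2 degrees of freedom.
    """
    if isinstance(X, pd.DataFrame):
        Xdf = X.astype(float)
    else:
        X = np.asarray(X, dtype=float)
        Xdf = pd.DataFrame(X, columns=[f"var{j}" for j in range(X.shape[1])])
    groups = np.asarray(groups)
    if Xdf.shape[0] < 2:
        raise ValueError("PLS-DA needs at least 2 samples")
    if Xdf.shape[0] != groups.shape[0]:
        raise ValueError("groups length must match the number of samples")
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("PLS-DA needs at least 2 groups")

    Xdf = _impute_half_minimum(Xdf)
    Xm = Xdf.to_numpy()
    Xc = Xm - Xm.mean(axis=0)
    sd = Xm.std(axis=0, ddof=1)
    if scaling == "auto":
        scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "none":
        scale = np.ones_like(sd)
    else:
        raise ValueError("scaling must be auto|pareto|none")
    Xs = Xc / scale

    Y = (groups[:, None] == levels[None, :]).astype(float)
    Yc = Y - Y.mean(axis=0)

    ss_x_total = float(np.sum(Xs**2))
    ss_y_total = float(np.sum(Yc**2))
    Xd = Xs.copy()
    Yd = Yc.copy()
    T = np.zeros((Xs.shape[0], n_components))
    W = np.zeros((Xs.shape[1], n_components))
    evx: list[float] = []
    evy: list[float] = []
    for a in range(n_components):
        u = Yd[:, np.argmax(Yd.var(axis=0))]
        if not np.any(u):
            u = Yd[:, 0]
        t = np.zeros(Xd.shape[0])
        for _ in range(max_iter):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t_new = Xd @ w
            q = Yd.T @ t_new
            qn = np.linalg.norm(q)
            if qn == 0:
                t = t_new
                break
            u_new = Yd @ q / (q @ q)
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t, u = t_new, u_new
        else:
            logger.warning("NIPALS did not converge for component %d", a + 1)
        tt = t @ t
        if tt == 0:
            logger.warning("component %d is degenerate; stopping extraction", a + 1)
            break
        p = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        T[:, a] = t
        W[:, a] = w
        evx.append(float(tt * (p @ p) / ss_x_total) if ss_x_total else 0.0)
        evy.append(float(tt * (c @ c) / ss_y_total) if ss_y_total else 0.0)

    comp_names = [f"comp{a + 1}" for a in range(n_components)]
    scores = pd.DataFrame(T, index=Xdf.index, columns=comp_names)
    loadings = pd.DataFrame(W, index=Xdf.columns, columns=comp_names)

    ellipses: list[GroupEllipse] = []
    if n_components >= 2:
        chi2_q = stats.chi2.ppf(conf_level, df=2)
        for g in levels:
            pts = T[groups == g, :2]
            if pts.shape[0] < 3:
                logger.warning("group %s has < 3 samples; no confidence ellipse", g)
                continue
            center = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False)
            vals, vecs = np.linalg.eigh(cov)
            order = np.argsort(vals)[::-1]
            vals, vecs = vals[order], vecs[:, order]
            semi = np.sqrt(np.maximum(vals, 0.0) * chi2_q)
            angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
            ellipses.append(
                GroupEllipse(
                    group=g,
                    center=(float(center[0]), float(center[1])),
                    semi_axes=(float(semi[0]), float(semi[1])),
                    angle_rad=angle,
                )
            )
    return PlsdaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_x=tuple(evx),
        explained_variance_y=tuple(evy),
        groups=groups,
        ellipses=ellipses,
    )


def pivot_exudate(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Donor x mediator concentration matrix and per-donor time labels."""
    required = {"donor", "time_h", "mediator", "concentration_pg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"exudate table is missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index="donor", columns="mediator", values="concentration_pg", aggfunc="mean"
    )
    times = table.drop_duplicates("donor").set_index("donor")["time_h"]
    times = times.reindex(wide.index)
    return wide, times.to_numpy()


# --------------------------------------------------------------------------
# Temporal testing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TemporalTestResult:
    """Kruskal-Wallis omnibus plus many-to-one post hoc for one mediator."""

    mediator: str
    h_statistic: float
    p_value: float
    comparisons: pd.DataFrame  # columns: time_h, z, p_raw, p_adj


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p value.

    All-identical data across every group gives H = 0, p = 1 rather
    than an error.
    """
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_many_to_one(
    groups: dict[object, np.ndarray],
    reference: object,
    correction: str = "holm",
) -> pd.DataFrame:
    """Dunn's rank-based z comparisons of each group against a reference.

    Pools all observations, ranks them with average ties, and compares
    each group's mean rank to the reference group's with the tie-adjusted
    variance; two-sided normal p values are adjusted for multiplicity
    (default Holm).
    """
    keys = list(groups)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    pooled = np.concatenate([groups[k] for k in keys])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks: dict[object, float] = {}
    pos = 0
    for k in keys:
        n_k = groups[k].size
        mean_ranks[k] = float(ranks[pos : pos + n_k].mean())
        pos += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_factor -= tie_term / (12.0 * (n_total - 1))

    rows = []
    n_ref = groups[reference].size
    for k in keys:
        if k == reference:
            continue
        se = np.sqrt(var_factor * (1.0 / groups[k].size + 1.0 / n_ref))
        z = (mean_ranks[k] - mean_ranks[reference]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((k, float(z), float(p)))
    df = pd.DataFrame(rows, columns=["time_h", "z", "p_raw"])
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=correction)[1]
    else:
        df["p_adj"] = []
    return df


def temporal_test(
    table: pd.DataFrame,
    mediator: str,
    reference_time: float = 0.0,
    correction: str = "holm",
) -> TemporalTestResult:
    """Time-course test for one mediator in a long-format exudate table.

    Kruskal-Wallis across time points, then Dunn's many-to-one
    comparisons of each time against ``reference_time`` with the chosen
    multiplicity correction.
    """
    sub = table[table["mediator"] == mediator]
    if sub.empty:
        raise ValueError(f"mediator {mediator!r} not present in the table")
    grouped = {
        t: g["concentration_pg"].to_numpy(dtype=float)
        for t, g in sub.groupby("time_h")
    }
    if len(grouped) < 2:
        raise ValueError("temporal test needs >= 2 time groups")
    if any(v.size < 2 for v in grouped.values()):
        raise ValueError("every time group needs >= 2 observations")
    h, p = kruskal_wallis(list(grouped.values()))
    comparisons = dunn_many_to_one(grouped, reference_time, correction=correction)
    return TemporalTestResult(
        mediator=mediator, h_statistic=h, p_value=p, comparisons=comparisons
    )
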