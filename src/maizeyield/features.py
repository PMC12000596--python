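"""Feature engineering from raw inputs to panel variables.

Covers the spectral vegetation indices, harmonic-regression monthly
compositing of 8-day satellite series, per-stage climate composites,
agricultural-mechanization rates and their GDP-based spatialization,
county-fertilizer disaggregation via an NDVI principal component, maize-mask
aggregation from 30 m to a 500 m grid, and planting-density centers.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .panel import STAGE_MONTHS

__all__ = [
    "compute_vi", "VI_NAMES", "harmonic_monthly_means", "composite_stage",
    "MechanizationAreas", "MechanizationRates", "mechanization_rates",
    "composite_mechanization_rate",
    "aggregate_maize_mask", "MaskAggregate", "THEORETICAL_MAX_PIXELS",
    "allocate_dfc", "fit_dcm_from_gdp", "predict_dcm", "DcmModel",
    "planting_density_center",
]


class VIDomainError(ValueError):
    """A vegetation-index formula was evaluated with a zero denominator."""


class FittingError(ValueError):
    """A regression design is rank deficient or under-determined."""


class MissingDataError(ValueError):
    """No samples fall within a requested compositing window."""


class DegeneratePcaError(ValueError):
    """The NDVI matrix has no usable principal structure."""


class DegenerateDesignError(ValueError):
    """A regression covariate is constant."""


VI_NAMES = ("NDVI", "EVI", "WDRVI", "GCVI", "GNDVI", "OSAVI")


def compute_vi(index: str, nir, r=None, g=None, b=None):
    """Evaluate one spectral vegetation index from surface reflectances.

    NDVI  = (NIR - R) / (NIR + R)
    EVI   = 2.5 (NIR - R) / (NIR + 6 R + 7.5 B + 1)
    WDRVI = (0.2 NIR - R) / (0.2 NIR + R)
    GCVI  = NIR / G - 1
    GNDVI = (NIR - G) / (NIR + G)
    OSAVI = (NIR - R) / (NIR + R + 0.16)

    Accepts scalars or broadcastable arrays; raises :class:`VIDomainError`
    if any denominator is zero.
    """
    nir = np.asarray(nir, dtype=float)
    r = None if r is None else np.asarray(r, dtype=float)
    g = None if g is None else np.asarray(g, dtype=float)
    b = None if b is None else np.asarray(b, dtype=float)

    def _need(*bands):
        for name, band in bands:
            if band is None:
                raise ValueError(f"{index} requires band {name}")

    if index == "NDVI":
        _need(("R", r))
        den = nir + r
        num = nir - r
    elif index == "EVI":
        _need(("R", r), ("B", b))
        den = nir + 6.0 * r + 7.5 * b + 1.0
        num = 2.5 * (nir - r)
    elif index == "WDRVI":
        _need(("R", r))
        den = 0.2 * nir + r
        num = 0.2 * nir - r
    elif index == "GCVI":
        _need(("G", g))
        den = g
        num = None
    elif index == "GNDVI":
        _need(("G", g))
        den = nir + g
        num = nir - g
    elif index == "OSAVI":
        _need(("R", r))
        den = nir + r + 0.16
        num = nir - r
    else:
        raise ValueError(f"unknown vegetation index {index!r}")
    if np.any(den == 0):
        raise VIDomainError(f"zero denominator evaluating {index}")
    if index == "GCVI":
        out = nir / g - 1.0
    else:
        out = num / den
    return out if out.ndim else float(out)


def _month_days(month: int) -> np.ndarray:
    """Day-of-year values of one calendar month in a non-leap year."""
    start = sum(calendar.monthrange(2001, m)[1] for m in range(1, month)) + 1
    return np.arange(start, start + calendar.monthrange(2001, month)[1])


def _day_to_month(days: np.ndarray) -> np.ndarray:
    edges = np.cumsum([calendar.monthrange(2001, m)[1] for m in range(1, 13)])
    return np.searchsorted(edges, np.asarray(days) - 1, side="right") + 1


def harmonic_monthly_means(
    days, values, months=STAGE_MONTHS, n_harmonics: int = 2, period: float = 365.0
):
    """Fit a harmonic regression to a within-year series and average it monthly.

    The design is an intercept plus `n_harmonics` sine/cosine pairs with an
    annual fundamental period; the fitted curve is evaluated on every day of
    each requested month (non-leap calendar) and averaged per month.

    Returns an array of one mean per requested month (the 5 growth stages by
    default).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.ndim != 1 or days.shape != values.shape:
        raise ValueError("days and values must be equal-length 1-D arrays")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    n_params = 2 * n_harmonics + 1
    if days.size < n_params:
        raise FittingError(
            f"need at least {n_params} samples for {n_harmonics} harmonics, got {days.size}"
        )

    def design(d):
        cols = [np.ones_like(d)]
        for k in range(1, n_harmonics + 1):
            w = 2.0 * np.pi * k * d / period
            cols += [np.cos(w), np.sin(w)]
        return np.column_stack(cols)

    A = design(days)
    if np.linalg.matrix_rank(A) < n_params:
        raise FittingError("rank-deficient harmonic design (samples too clustered)")
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    return np.array(
        [(design(_month_days(m).astype(float)) @ coef).mean() for m in months]
    )


def composite_stage(days, values, month: int, method: str):
    """Mean or sum of the in-month samples of one variable.

    `method` is the variable's declared composite rule ("mean" for satellite
    indices and Pet/Vap/Vpd, "sum" for Tmin/Tmax/Pre/Pdsi).
    """
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    in_month = _day_to_month(days) == month
    if not in_month.any():
        raise MissingDataError(f"no samples in month {month}")
    sel = values[in_month]
    if method == "mean":
        return float(sel.mean())
    if method == "sum":
        return float(sel.sum())
    raise ValueError(f"unknown composite method {method!r}")


# -- agricultural mechanization ------------------------------------------------


@dataclass(frozen=True)
class MechanizationAreas:
    """Machine-worked areas (same unit each): plowed, sown, total sown,
    no-till, harvested, crop-loss."""

    plowed: float
    sown: float
    total_sown: float
    no_till: float
    harvested: float
    crop_loss: float


@dataclass(frozen=True)
class MechanizationRates:
    """Plowing/sowing/harvest rates and their weighted composite.

    `suspect` flags any rate above 1, which the harvest-rate formula
    R_h = A_h / (A_h - A_l) produces whenever crop-loss area is positive; the
    formula is applied as published and flagged rather than silently altered.
    """

    plowing: float
    sowing: float
    harvest: float
    composite: float
    suspect: bool


def composite_mechanization_rate(r_p: float, r_s: float, r_h: float) -> float:
    """Weighted composite of plowing/sowing/harvest rates:
    R_c = 0.4 R_p + 0.3 R_s + 0.3 R_h."""
    return 0.4 * r_p + 0.3 * r_s + 0.3 * r_h


def mechanization_rates(
    areas: MechanizationAreas, harvest_denominator: str = "published"
) -> MechanizationRates:
    """Compute mechanization rates and their weighted composite.

    R_p = A_p / (A_s - A_n);  R_s = A_s / A_t;  R_h = A_h / (A_h - A_l);
    R_c = 0.4 R_p + 0.3 R_s + 0.3 R_h.

    `harvest_denominator="total"` switches R_h to A_h / (A_t - A_l), a
    plausible intent for the published formula, but the published form is the
    default.
    """
    a = areas
    if min(a.plowed, a.sown, a.total_sown, a.no_till, a.harvested, a.crop_loss) < 0:
        raise ValueError("areas must be nonnegative")
    if a.sown > a.total_sown:
        raise ValueError("sown area exceeds total sown area")
    den_p = a.sown - a.no_till
    if den_p <= 0:
        raise ValueError("plowing-rate denominator (A_s - A_n) must be positive")
    if a.total_sown <= 0:
        raise ValueError("sowing-rate denominator (A_t) must be positive")
    if harvest_denominator == "published":
        den_h = a.harvested - a.crop_loss
    elif harvest_denominator == "total":
        den_h = a.total_sown - a.crop_loss
    else:
        raise ValueError("harvest_denominator must be 'published' or 'total'")
    if den_h <= 0:
        raise ValueError("harvest-rate denominator must be positive")
    r_p = a.plowed / den_p
    r_s = a.sown / a.total_sown
    r_h = a.harvested / den_h
    r_c = composite_mechanization_rate(r_p, r_s, r_h)
    return MechanizationRates(
        plowing=r_p, sowing=r_s, harvest=r_h, composite=r_c,
        suspect=max(r_p, r_s, r_h) > 1.0,
    )


# -- mask aggregation ----------------------------------------------------------

#: maximum number of 30 m pixels per 500 m cell: floor((500/30)^2)
THEORETICAL_MAX_PIXELS = int((500 / 30) ** 2)  # == 277

#: fine pixels per coarse-cell edge used by the toy tiling (17^2 = 289 >= 277)
DEFAULT_BLOCK_EDGE = 17


@dataclass
class MaskAggregate:
    """Coarse-grid aggregation of a binary maize mask."""

    counts: np.ndarray
    fractions: np.ndarray
    is_maize: np.ndarray
    threshold: float
    max_pixels: int


def aggregate_maize_mask(
    mask: np.ndarray,
    block_edge: int = DEFAULT_BLOCK_EDGE,
    threshold: float = 0.8,
    max_pixels: int = THEORETICAL_MAX_PIXELS,
) -> MaskAggregate:
    """Aggregate a binary 30 m maize mask onto a coarse grid.

    Each `block_edge` x `block_edge` block of fine pixels becomes one coarse
    cell; the maize-pixel count is capped at `max_pixels` (the theoretical
    maximum per 500 m cell), the fraction is count / max_pixels, and a cell is
    classified maize iff fraction >= threshold.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask raster")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    rows, cols = mask.shape
    if rows % block_edge or cols % block_edge:
        raise ValueError(
            f"mask shape {mask.shape} does not tile evenly into {block_edge}-pixel blocks"
        )
    coarse = mask.reshape(rows // block_edge, block_edge, cols // block_edge, block_edge)
    counts = np.minimum(coarse.sum(axis=(1, 3)), max_pixels)
    fractions = counts / max_pixels
    return MaskAggregate(
        counts=counts, fractions=fractions, is_maize=fractions >= threshold,
        threshold=threshold, max_pixels=max_pixels,
    )


# -- fertilizer disaggregation -------------------------------------------------


def allocate_dfc(
    county_fertilizer_total: float,
    maize_area_share: float,
    ndvi_series_by_cell: np.ndarray,
) -> np.ndarray:
    """Distribute a county's maize-specific fertilizer total over grid cells.

    The maize total is `county_fertilizer_total * maize_area_share`.  Cells
    are weighted by their scores on the second principal component of the
    (cell x timepoint) NDVI matrix: the score vector's sign is chosen so it
    correlates nonnegatively with mean cell NDVI, scores are shifted by their
    minimum to be nonnegative and renormalized to sum to one.  When the
    second component is degenerate (no variation beyond the first), the
    allocation falls back to uniform weights.  The per-cell values sum to the
    maize total exactly (conservation).
    """
    X = np.asarray(ndvi_series_by_cell, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a (cells x timepoints) matrix with >= 2 of each")
    if county_fertilizer_total < 0 or not (0 <= maize_area_share <= 1):
        raise ValueError("invalid county total or maize area share")
    total = county_fertilizer_total * maize_area_share
    centered = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    if S[0] < 1e-12:
        raise DegeneratePcaError("all NDVI rows identical; no principal component")
    scores = U[:, 1] * S[1] if len(S) > 1 else np.zeros(X.shape[0])
    mean_ndvi = X.mean(axis=1)
    if np.dot(scores, mean_ndvi - mean_ndvi.mean()) < 0:
        scores = -scores
    shifted = scores - scores.min()
    if shifted.max() < 1e-12 * max(S[0], 1.0):
        weights = np.full(X.shape[0], 1.0 / X.shape[0])
    else:
        weights = shifted / shifted.sum()
    return total * weights


# -- mechanization spatialization ---------------------------------------------


@dataclass(frozen=True)
class DcmModel:
    """Affine GDP -> composite-mechanization-rate model."""

    slope: float
    intercept: float
    r_squared: float


def fit_dcm_from_gdp(gdp, r_c) -> DcmModel:
    """Ordinary least squares of composite mechanization rate on county GDP."""
    gdp = np.asarray(gdp, dtype=float)
    r_c = np.asarray(r_c, dtype=float)
    if gdp.shape != r_c.shape or gdp.ndim != 1 or gdp.size < 3:
        raise ValueError("need >= 3 (GDP, R_c) pairs")
    if np.ptp(gdp) == 0:
        raise DegenerateDesignError("GDP is constant; slope not identifiable")
    fit = _sps.linregress(gdp, r_c)
    return DcmModel(slope=float(fit.slope), intercept=float(fit.intercept),
                    r_squared=float(fit.rvalue**2))


def predict_dcm(model: DcmModel, gdp):
    gdp = np.asarray(gdp, dtype=float)
    out = model.intercept + model.slope * gdp
    return out if out.ndim else float(out)


# -- planting-density centers --------------------------------------------------


def planting_density_center(density: np.ndarray, bounding_box=None):
    """Normalized (lon, lat) of the densest maize cell.

    `density` is a (rows x cols) grid of maize pixel counts per km², with
    row 0 at the southern edge and column 0 at the western edge.  Ties break
    to the smallest row-major index.  Coordinates are min-max normalized over
    the grid of cell centers, so the minimum-corner cell maps to (0, 0); a
    single-row or single-column grid maps to 0.5 on that axis.  The bounding
    box only fixes the geographic interpretation and does not affect the
    normalized output.
    """
    density = np.asarray(density, dtype=float)
    if density.ndim != 2:
        raise ValueError("density must be a 2-D grid")
    if not (density > 0).any():
        raise ValueError("all-zero planting density")
    row, col = np.unravel_index(np.argmax(density), density.shape)
    nrows, ncols = density.shape
    lon = col / (ncols - 1) if ncols > 1 else 0.5
    lat = row / (nrows - 1) if nrows > 1 else 0.5
    return float(lon), float(lat)
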