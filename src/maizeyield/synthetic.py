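"""Synthetic county-year panels, reflectance series and toy maize masks.

The generator emulates the structure of the real inputs — smooth seasonal
vegetation-index curves peaking mid-season, climate variables with year
anomalies and optional drought years, static soil/modernization fields per
county — and produces yield from a known function of the stage-4 canopy
signal, stage-3 precipitation, mechanization degree, soil organic carbon, a
latitudinal trend and a mild vigor x precipitation interaction, plus county
and year effects and Gaussian noise.  The planted coefficients and the causal
feature list are returned as ground truth so recovery can be tested.

Pdsi and Vap are always generated as pure noise, giving known-null features
for importance checks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .panel import (DYNAMIC_VARIABLES, FeaturePanel, N_DYNAMIC, N_PERIODIC,
                    N_STAGES)

#: mid-month day of year of each growth stage (May..September, non-leap)
STAGE_MID_DAYS = np.array([136.0, 166.5, 197.0, 228.0, 258.5])

#: within-season shape of the thermal variables, peaking at stage 3
_LST_SHAPE = np.array([0.55, 0.85, 1.00, 0.92, 0.65])
_PRE_MEAN = np.array([60.0, 90.0, 140.0, 120.0, 70.0])
_PRE_SD_FRAC = 0.25
_PET_MEAN = np.array([90.0, 110.0, 130.0, 120.0, 95.0])
_VPD_MEAN = np.array([0.8, 1.0, 1.3, 1.2, 0.9])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic panel.

    Effect sizes are on the t/ha scale per standard deviation of the latent
    driver; the canopy-vigor latent is observed through the stage-3/4
    vegetation indices.
    """

    n_counties: int = 150
    year_start: int = 2001
    year_end: int = 2021
    drought_years: tuple = (2014,)
    #: t/ha per sd of canopy vigor (observed via EVI and peers at S3/S4)
    effect_vigor: float = 1.2
    #: t/ha per sd of stage-3 precipitation
    effect_pre: float = 0.6
    #: t/ha per sd of comprehensive mechanization degree
    effect_dcm: float = 0.5
    #: t/ha per sd of soil organic carbon
    effect_soc: float = 0.3
    #: t/ha across the full south-north extent
    effect_lat: float = 0.8
    #: vigor x stage-3 precipitation interaction
    effect_interaction: float = 0.25
    base_yield: float = 8.0
    county_sd: float = 0.3
    year_sd: float = 0.15
    noise_sd: float = 0.5
    #: canopy curve: Gaussian bump over day of year
    peak_day: float = 200.0
    peak_jitter: float = 6.0
    #: phenology gradient: peak day shifts by +/- this many days across the
    #: full south-north extent (later peaks in the north), so the informative
    #: growth stage varies by county within S3-S4
    phenology_lat_shift: float = 18.0
    curve_width: float = 26.0
    vi_amplitude: float = 0.45
    vi_amplitude_per_vigor: float = 0.08
    drought_vigor_drop: float = 1.2
    drought_pre_factor: float = 0.5
    drought_lst_boost: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 2:
            raise ValueError("need at least 2 counties")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("need at least 3 years")


def generate_panel(config: SyntheticConfig) -> tuple[FeaturePanel, dict]:
    """Generate a (FeaturePanel, ground_truth) pair for the configured study."""
    rng = np.random.default_rng(config.seed)
    nc = config.n_counties
    years = np.arange(config.year_start, config.year_end + 1)
    ny = len(years)
    n = nc * ny

    # static county fields
    county_ids = np.array([f"C{i:04d}" for i in range(nc)])
    lon = rng.uniform(0, 1, nc)
    lat = rng.uniform(0, 1, nc)
    tex = rng.integers(1, 13, nc).astype(float)
    frac = rng.dirichlet(np.full(3, 2.0), size=nc) * 100.0
    soc = rng.uniform(0.5, 6.0, nc)
    soc_z = (soc - 3.25) / ((6.0 - 0.5) / np.sqrt(12.0))
    dcm_latent = rng.normal(0, 1, nc)
    dcm = np.clip(150.0 + 40.0 * dcm_latent, 60.0, 290.0)
    dfc = rng.uniform(10, 90, nc)
    county_resid = rng.normal(0, config.county_sd, nc)
    peak_c = (config.peak_day
              + config.phenology_lat_shift * (lat - 0.5) * 2.0
              + rng.normal(0, 1, nc) * config.peak_jitter)

    year_eff = rng.normal(0, config.year_sd, ny)
    is_drought = np.isin(years, np.asarray(config.drought_years, dtype=int))

    # county-year latents, (nc, ny)
    vigor = rng.normal(0, 1, (nc, ny)) - config.drought_vigor_drop * is_drought
    pre = rng.normal(_PRE_MEAN, _PRE_SD_FRAC * _PRE_MEAN, (nc, ny, N_STAGES))
    pre = np.maximum(pre, 0.0)
    pre[:, is_drought, :] *= config.drought_pre_factor
    pre3_z = (pre[:, :, 2] - _PRE_MEAN[2]) / (_PRE_SD_FRAC * _PRE_MEAN[2])

    bump = np.exp(-((STAGE_MID_DAYS - peak_c[:, None]) ** 2)
                  / (2.0 * config.curve_width**2))       # (nc, 5)
    amp = config.vi_amplitude + config.vi_amplitude_per_vigor * vigor  # (nc, ny)
    curve = amp[:, :, None] * bump[:, None, :]           # (nc, ny, 5)

    def vi(base, scale, noise):
        return base + scale * curve + rng.normal(0, noise, (nc, ny, N_STAGES))

    dynamic = np.empty((nc, ny, N_STAGES, N_DYNAMIC))
    cols = {v: i for i, v in enumerate(DYNAMIC_VARIABLES)}
    dynamic[..., cols["NDVI"]] = vi(0.18, 1.00, 0.010)
    dynamic[..., cols["EVI"]] = vi(0.12, 0.90, 0.010)
    dynamic[..., cols["GCVI"]] = vi(0.30, 6.00, 0.050)
    dynamic[..., cols["GNDVI"]] = vi(0.15, 0.80, 0.010)
    dynamic[..., cols["WDRVI"]] = vi(-0.40, 1.10, 0.010)
    dynamic[..., cols["OSAVI"]] = vi(0.15, 0.85, 0.010)
    dynamic[..., cols["SIF"]] = vi(0.05, 0.50, 0.005)
    lst = (14.0 + 12.0 * _LST_SHAPE + rng.normal(0, 0.8, (nc, ny, N_STAGES))
           + config.drought_lst_boost * is_drought[None, :, None])
    dynamic[..., cols["LST"]] = lst
    dynamic[..., cols["Tmin"]] = 30.0 * (8.0 + 10.0 * _LST_SHAPE) + rng.normal(0, 10, (nc, ny, N_STAGES))
    dynamic[..., cols["Tmax"]] = 30.0 * (18.0 + 10.0 * _LST_SHAPE) + rng.normal(0, 10, (nc, ny, N_STAGES))
    dynamic[..., cols["Pre"]] = pre
    dynamic[..., cols["Pdsi"]] = rng.normal(0, 1, (nc, ny, N_STAGES))
    dynamic[..., cols["Pet"]] = _PET_MEAN + rng.normal(0, 5, (nc, ny, N_STAGES))
    dynamic[..., cols["Vap"]] = rng.normal(10, 1, (nc, ny, N_STAGES))
    dynamic[..., cols["Vpd"]] = _VPD_MEAN + rng.normal(0, 0.05, (nc, ny, N_STAGES))

    signal = (
        config.base_yield
        + config.effect_vigor * vigor
        + config.effect_pre * pre3_z
        + config.effect_dcm * dcm_latent[:, None]
        + config.effect_soc * soc_z[:, None]
        + config.effect_lat * (lat[:, None] - 0.5) * 2.0
        + config.effect_interaction * vigor * pre3_z
        + county_resid[:, None]
    )
    yields = np.maximum(
        0.0, signal + year_eff[None, :] + rng.normal(0, config.noise_sd, (nc, ny))
    )

    periodic = np.column_stack([tex, frac[:, 0], frac[:, 1], frac[:, 2],
                                soc, lon, lat, dfc, dcm])
    assert periodic.shape[1] == N_PERIODIC

    panel = FeaturePanel(
        county_ids=np.repeat(county_ids, ny),
        years=np.tile(years, nc),
        dynamic=dynamic.reshape(n, N_STAGES, N_DYNAMIC),
        periodic=np.repeat(periodic, ny, axis=0),
        yields=yields.reshape(n),
    )
    panel.validate()

    mean_sig_normal = float(signal[:, ~is_drought].mean())
    mean_sig_drought = float(signal[:, is_drought].mean()) if is_drought.any() else float("nan")
    ground_truth = {
        "coefficients": {
            "vigor": config.effect_vigor, "Pre_S3": config.effect_pre,
            "DCM": config.effect_dcm, "soc_pct": config.effect_soc,
            "lat_norm": config.effect_lat,
            "vigor_x_Pre_S3": config.effect_interaction,
        },
        "causal_features": ["EVI_S4", "Pre_S3", "DCM", "soc_pct", "lat_norm"],
        "noise_features": (
            [f"Pdsi_S{s}" for s in range(1, 6)] + [f"Vap_S{s}" for s in range(1, 6)]
        ),
        "interaction": "vigor (EVI_S4 proxy) x Pre_S3",
        "mean_signal_normal": mean_sig_normal,
        "mean_signal_drought": mean_sig_drought,
        "expected_drought_gap": mean_sig_normal - mean_sig_drought,
        "config": asdict(config),
    }
    return panel, ground_truth


def generate_reflectance_series(
    n_cells: int = 4,
    seed: int = 0,
    peak_day: float = 200.0,
    curve_width: float = 32.0,
    amplitude: float = 0.8,
) -> pd.DataFrame:
    """Per-cell 8-day reflectance series (columns cell_id, day, NIR, R, G, B).

    Reflectances are smooth functions of a seasonal greenness bump so the
    NDVI computed from them follows the planted curve and peaks in the
    planted month.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(1, 366, 8)
    rows = []
    for cell in range(n_cells):
        a = amplitude * rng.uniform(0.7, 1.0)
        green = a * np.exp(-((days - peak_day) ** 2) / (2 * curve_width**2))
        rows.append(pd.DataFrame({
            "cell_id": cell,
            "day": days,
            "NIR": 0.15 + 0.35 * green,
            "R": 0.15 - 0.10 * green,
            "G": 0.12 - 0.05 * green,
            "B": np.full(days.shape, 0.05),
        }))
    return pd.concat(rows, ignore_index=True)


def generate_maize_mask(
    target_counts: np.ndarray, block_edge: int = 17, seed: int = 0
) -> np.ndarray:
    """Binary 30 m mask whose per-coarse-cell maize counts match a request.

    `target_counts` is a (rows x cols) integer grid; each coarse cell gets
    exactly that many maize pixels, placed by a seeded draw within its
    `block_edge` x `block_edge` block.
    """
    target_counts = np.asarray(target_counts, dtype=int)
    if target_counts.ndim != 2:
        raise ValueError("target_counts must be 2-D")
    if target_counts.min() < 0 or target_counts.max() > block_edge**2:
        raise ValueError(f"counts must lie in [0, {block_edge**2}]")
    rng = np.random.default_rng(seed)
    rows, cols = target_counts.shape
    mask = np.zeros((rows * block_edge, cols * block_edge), dtype=int)
    for i in range(rows):
        for j in range(cols):
            flat = rng.choice(block_edge**2, size=target_counts[i, j], replace=False)
            r, c = np.divmod(flat, block_edge)
            mask[i * block_edge + r, j * block_edge + c] = 1
    return mask
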