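"""County-year feature panel: canonical data model, CSV I/O and normalization.

A panel row is one (county, year) observation holding a dynamic cube of
15 variables x 5 monthly growth stages (S1..S5 = May..September), a vector of
9 periodic variables that change yearly or every five years (soil texture and
fractions, soil organic carbon, normalized planting-density-center
coordinates, fertilizer-consumption degree DFC and comprehensive
mechanization degree DCM), and the yield label in t/ha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DYNAMIC_VARIABLES = (
    "NDVI", "EVI", "GCVI", "GNDVI", "WDRVI", "OSAVI", "SIF", "LST",
    "Tmin", "Tmax", "Pre", "Pdsi", "Pet", "Vap", "Vpd",
)
PERIODIC_VARIABLES = (
    "texture_class", "clay_pct", "silt_pct", "sand_pct", "soc_pct",
    "lon_norm", "lat_norm", "DFC", "DCM",
)
STAGE_LABELS = ("S1", "S2", "S3", "S4", "S5")
#: calendar month of each growth stage (May..September)
STAGE_MONTHS = (5, 6, 7, 8, 9)
N_STAGES = len(STAGE_LABELS)
N_DYNAMIC = len(DYNAMIC_VARIABLES)
N_PERIODIC = len(PERIODIC_VARIABLES)

#: periodic variables already on a [0, 1] scale, never z-scored
COORDINATE_VARIABLES = ("lon_norm", "lat_norm")

#: per-stage composite method for each dynamic variable (mean for satellite
#: indices and Pet/Vap/Vpd, monthly sum for Tmin/Tmax/Pre/Pdsi)
COMPOSITE_METHODS = {
    **{v: "mean" for v in ("NDVI", "EVI", "GCVI", "GNDVI", "WDRVI", "OSAVI", "SIF", "LST")},
    **{v: "sum" for v in ("Tmin", "Tmax", "Pre", "Pdsi")},
    **{v: "mean" for v in ("Pet", "Vap", "Vpd")},
}


class SchemaError(ValueError):
    """A panel file does not match the variable registry."""


class IntegrityError(ValueError):
    """A panel violates a structural invariant (e.g. duplicated county-year)."""


class DegenerateVariableError(ValueError):
    """A variable has zero variance and cannot be z-scored."""


def dynamic_columns() -> list[str]:
    """Column names of the flattened dynamic cube, variable-major."""
    return [f"{v}_{s}" for v in DYNAMIC_VARIABLES for s in STAGE_LABELS]


def feature_columns() -> list[str]:
    """All 84 feature column names in canonical order."""
    return dynamic_columns() + list(PERIODIC_VARIABLES)


@dataclass
class FeaturePanel:
    """Ordered collection of county-year records with aligned numeric arrays.

    Attributes
    ----------
    county_ids : (n,) array of opaque county identifiers (strings or ints).
    years : (n,) int array.
    dynamic : (n, 5, 15) array — stages x dynamic variables.
    periodic : (n, 9) array.
    yields : (n,) array in t/ha; NaN marks a record in prediction mode.
    """

    county_ids: np.ndarray
    years: np.ndarray
    dynamic: np.ndarray
    periodic: np.ndarray
    yields: np.ndarray

    def __post_init__(self):
        self.county_ids = np.asarray(self.county_ids)
        self.years = np.asarray(self.years, dtype=int)
        self.dynamic = np.asarray(self.dynamic, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def n_records(self) -> int:
        return len(self.years)

    def validate(self, allow_missing_yield: bool = True, clean: bool = True) -> None:
        """Check the panel invariants, raising on the first violation.

        With ``clean=True`` any NaN in the feature blocks is an error; the
        sentinel used by in-season masking is 0, not NaN, so masked panels
        remain clean.
        """
        n = self.n_records
        shapes = {
            "county_ids": (n,), "years": (n,),
            "dynamic": (n, N_STAGES, N_DYNAMIC),
            "periodic": (n, N_PERIODIC), "yields": (n,),
        }
        for name, want in shapes.items():
            got = getattr(self, name).shape
            if got != want:
                raise IntegrityError(f"{name} has shape {got}, expected {want}")
        keys = list(zip(self.county_ids.tolist(), self.years.tolist()))
        if len(set(keys)) != n:
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate (county, year) pairs: {dupes}")
        if clean:
            bad = np.flatnonzero(
                ~np.isfinite(self.dynamic).all(axis=(1, 2))
                | ~np.isfinite(self.periodic).all(axis=1)
            )
            if bad.size:
                raise IntegrityError(
                    f"non-finite feature values in rows {bad.tolist()}"
                )
        lon = self.periodic[:, PERIODIC_VARIABLES.index("lon_norm")]
        lat = self.periodic[:, PERIODIC_VARIABLES.index("lat_norm")]
        if len(lon) and (np.nanmin([lon, lat]) < -1e-12 or np.nanmax([lon, lat]) > 1 + 1e-12):
            raise IntegrityError("normalized coordinates outside [0, 1]")
        with np.errstate(invalid="ignore"):
            neg = np.flatnonzero(self.yields < 0)
        if neg.size:
            raise IntegrityError(f"negative yields in rows {neg.tolist()}")
        if not allow_missing_yield and np.isnan(self.yields).any():
            raise IntegrityError("missing yields not allowed in this context")

    # -- pandas / CSV ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        n = self.n_records
        data = {"county_id": self.county_ids, "year": self.years}
        flat = self.dynamic.transpose(0, 2, 1).reshape(n, N_DYNAMIC * N_STAGES)
        for j, col in enumerate(dynamic_columns()):
            data[col] = flat[:, j]
        for j, col in enumerate(PERIODIC_VARIABLES):
            data[col] = self.periodic[:, j]
        data["yield_t_ha"] = self.yields
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, validate: bool = True) -> "FeaturePanel":
        required = ["county_id", "year"] + feature_columns() + ["yield_t_ha"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        n = len(frame)
        dyn = frame[dynamic_columns()].to_numpy(float).reshape(n, N_DYNAMIC, N_STAGES)
        panel = cls(
            county_ids=frame["county_id"].to_numpy(),
            years=frame["year"].to_numpy(int),
            dynamic=dyn.transpose(0, 2, 1),
            periodic=frame[list(PERIODIC_VARIABLES)].to_numpy(float),
            yields=frame["yield_t_ha"].to_numpy(float),
        )
        if validate:
            panel.validate()
        return panel

    def subset(self, mask: np.ndarray) -> "FeaturePanel":
        mask = np.asarray(mask)
        return FeaturePanel(
            self.county_ids[mask], self.years[mask], self.dynamic[mask],
            self.periodic[mask], self.yields[mask],
        )

    def copy(self) -> "FeaturePanel":
        return FeaturePanel(
            self.county_ids.copy(), self.years.copy(), self.dynamic.copy(),
            self.periodic.copy(), self.yields.copy(),
        )

    def feature_matrix(self) -> np.ndarray:
        """(n, 84) flat matrix in `feature_columns()` order."""
        n = self.n_records
        flat = self.dynamic.transpose(0, 2, 1).reshape(n, N_DYNAMIC * N_STAGES)
        return np.concatenate([flat, self.periodic], axis=1)

    @classmethod
    def from_feature_matrix(cls, template: "FeaturePanel", X: np.ndarray) -> "FeaturePanel":
        """Rebuild a panel from a flat (n, 84) matrix, keeping ids/yields."""
        n = len(template)
        dyn = X[:, : N_DYNAMIC * N_STAGES].reshape(n, N_DYNAMIC, N_STAGES)
        return cls(
            template.county_ids.copy(), template.years.copy(),
            dyn.transpose(0, 2, 1), X[:, N_DYNAMIC * N_STAGES:].copy(),
            template.yields.copy(),
        )


def read_panel(path, validate: bool = True) -> FeaturePanel:
    """Read a CSV panel, validating schema and integrity."""
    frame = pd.read_csv(path)
    return FeaturePanel.from_frame(frame, validate=validate)


def write_panel(panel: FeaturePanel, path) -> None:
    """Write a CSV panel with the canonical, deterministic column order."""
    panel.to_frame().to_csv(path, index=False)


def drop_yield_outliers(panel: FeaturePanel, k: float = 4.0) -> FeaturePanel:
    """Exclusion hook: drop records with yield outside mean +/- k*sd.

    A coarse, configurable stand-in for an initial quality screen on county
    yield statistics; records with missing yield are kept.
    """
    y = panel.yields
    ok = np.isnan(y)
    obs = y[~np.isnan(y)]
    if obs.size:
        mu, sd = obs.mean(), obs.std()
        ok = ok | (np.abs(y - mu) <= k * sd)
    return panel.subset(ok)


@dataclass
class NormalizationStats:
    """Per-feature mean/sd fitted on a training subset (coordinates excluded)."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list = field(default_factory=feature_columns)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                "columns": list(self.columns)}


def normalize_panel(
    panel: FeaturePanel, stats: NormalizationStats | None = None
) -> tuple[FeaturePanel, NormalizationStats]:
    """Z-score every feature column except the already-[0,1] coordinates.

    When `stats` is given (fitted on a training subset) they are applied
    unchanged, so held-out data never leaks into the normalization.
    """
    cols = feature_columns()
    X = panel.feature_matrix()
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        for j, col in enumerate(cols):
            if col in COORDINATE_VARIABLES:
                mean[j], sd[j] = 0.0, 1.0
            elif sd[j] == 0.0:
                raise DegenerateVariableError(
                    f"variable {col!r} has zero variance on the fitting subset"
                )
        stats = NormalizationStats(mean=mean, sd=sd, columns=cols)
    Z = (X - stats.mean) / stats.sd
    return FeaturePanel.from_feature_matrix(panel, Z), stats


def denormalize_panel(panel: FeaturePanel, stats: NormalizationStats) -> FeaturePanel:
    X = panel.feature_matrix() * stats.sd + stats.mean
    return FeaturePanel.from_feature_matrix(panel, X)
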