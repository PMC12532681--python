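"""Rotating-panel survey data model and delimited-text I/O.

A rotating-panel survey visits a fixed fraction of its stations each year,
so that every station recurs at a fixed revisit interval (six years in the
Swedish Lake Survey design this package emulates).  Observations are kept in
long format -- one row per (station, year, variable) -- together with
per-station catchment attributes and annual climate series.

The module also implements the two pre-processing rules that operate on raw
observations before any transformation: substitution of values censored at
laboratory reporting limits, and removal of stations with too few
observations inside the trend window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Controlled vocabulary of water-chemistry variables.
CHEMISTRY_VARIABLES: tuple[str, ...] = (
    "pH",
    "alkalinity",
    "conductivity",
    "Mg",
    "Cl",
    "Ca",
    "Na",
    "SO4",
)

#: Variables that are log10-transformed prior to analysis (all but pH).
LOG10_VARIABLES: tuple[str, ...] = tuple(v for v in CHEMISTRY_VARIABLES if v != "pH")

#: Canonical observation columns, in canonical order.
OBS_COLUMNS = ("station_id", "year", "variable", "value", "below_limit", "reporting_limit")

#: The 15 land-use classes of the catchment composition, as ``lu_<class>``
#: columns in the attribute table.
LANDUSE_CLASSES: tuple[str, ...] = (
    "coniferous_forest",
    "deciduous_forest",
    "mixed_forest",
    "forest_on_wetland",
    "clearcut",
    "arable",
    "pasture",
    "open_wetland",
    "urban",
    "artificial_surfaces",
    "water",
    "alpine_bare",
    "alpine_heath",
    "grassland",
    "shrub",
)

ATTR_COLUMNS = ("station_id", "easting", "northing", "elevation", "catchment_area") + tuple(
    f"lu_{c}" for c in LANDUSE_CLASSES
)

CLIMATE_COLUMNS = ("station_id", "year", "temperature", "precipitation")

#: Default study horizon for observation years.
DEFAULT_HORIZON = (2008, 2023)


class SurveyDataError(Exception):
    """Base class for survey-data errors."""


class SchemaError(SurveyDataError):
    """A required column is missing or the schema is inconsistent."""


class DuplicateRecordError(SurveyDataError):
    """More than one observation for the same (station, year, variable)."""


class LimitPolicyError(SurveyDataError):
    """A below-limit observation cannot be resolved by the limit policy."""


class EmptyPanelError(SurveyDataError):
    """Filtering removed every station."""


@dataclass(frozen=True)
class LimitPolicy:
    """Reporting-limit substitution policy.

    The generic rule replaces each censored value with half of its own
    reporting limit.  Chloride is handled differently because its reporting
    limit changed over time: *all* values at or below the historical maximum
    limit are replaced with half that maximum, flagged or not.

    Parameters
    ----------
    cl_max_limit:
        Historical maximum reporting limit for Cl, or None to apply the
        generic rule to Cl as well.
    """

    cl_max_limit: float | None = None


@dataclass
class SurveyPanel:
    """Long-format survey observations with attached station registries.

    Attributes
    ----------
    observations:
        DataFrame with columns ``station_id, year, variable, value,
        below_limit, reporting_limit``; unique on (station_id, year,
        variable).
    attributes:
        Per-station catchment attributes (coordinates, elevation, catchment
        area, 15 land-use percentage columns), or None.
    climate:
        Long-format annual climate series (station_id, year, temperature,
        precipitation), or None.
    """

    observations: pd.DataFrame
    attributes: pd.DataFrame | None = None
    climate: pd.DataFrame | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise SchemaError(f"observations missing columns: {missing}")
        dup = obs.duplicated(subset=["station_id", "year", "variable"])
        if dup.any():
            rows = obs.index[dup].tolist()[:10]
            raise DuplicateRecordError(
                f"duplicate (station, year, variable) records at rows {rows}"
            )
        if self.attributes is not None:
            observed = set(obs["station_id"])
            known = set(self.attributes["station_id"])
            orphans = observed - known
            if orphans:
                raise SchemaError(
                    f"{len(orphans)} observed stations lack attributes, "
                    f"e.g. {sorted(orphans)[:5]}"
                )

    @property
    def stations(self) -> list:
        return sorted(self.observations["station_id"].unique())

    def copy(self) -> "SurveyPanel":
        return SurveyPanel(
            observations=self.observations.copy(),
            attributes=None if self.attributes is None else self.attributes.copy(),
            climate=None if self.climate is None else self.climate.copy(),
            diagnostics=list(self.diagnostics),
        )

    def variable(self, name: str) -> pd.DataFrame:
        """Observations of a single variable, sorted by station and year."""
        sub = self.observations[self.observations["variable"] == name]
        return sub.sort_values(["station_id", "year"]).reset_index(drop=True)


def _attribute_year(year: np.ndarray, month: np.ndarray | None) -> np.ndarray:
    """Assign January samples to the previous autumn's survey year."""
    year = np.asarray(year, dtype=int)
    if month is None:
        return year
    month = np.asarray(month)
    out = year.copy()
    out[month == 1] -= 1
    return out


def _validate_observations(
    obs: pd.DataFrame, horizon: tuple[int, int]
) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows violating observation invariants; return diagnostics.

    Rows are reported by their (1-based, post-header) position in the
    source table.
    """
    diags: list[str] = []
    keep = np.ones(len(obs), dtype=bool)
    row_no = np.arange(1, len(obs) + 1)

    bad_year = (obs["year"] < horizon[0]) | (obs["year"] > horizon[1])
    for r in row_no[bad_year.to_numpy()]:
        diags.append(f"row {r}: year outside study horizon {horizon}")
    keep &= ~bad_year.to_numpy()

    # a value must be present unless the row is censored with a known limit
    censored = obs["below_limit"].to_numpy(dtype=bool)
    no_value = obs["value"].isna().to_numpy()
    no_limit = obs["reporting_limit"].isna().to_numpy()
    bad_value = no_value & ~(censored & ~no_limit)
    for r in row_no[bad_value]:
        diags.append(f"row {r}: missing value on an uncensored observation")
    keep &= ~bad_value

    bad_cens = censored & no_limit
    for r in row_no[bad_cens]:
        diags.append(f"row {r}: below-limit flag without a reporting limit")
    keep &= ~bad_cens

    is_ph = (obs["variable"] == "pH").to_numpy()
    ph_val = obs["value"].to_numpy(dtype=float)
    bad_ph = is_ph & ~np.isnan(ph_val) & ((ph_val <= 0) | (ph_val >= 14))
    for r in row_no[bad_ph]:
        diags.append(f"row {r}: pH outside (0, 14)")
    keep &= ~bad_ph

    return obs.loc[keep].reset_index(drop=True), diags


def read_survey(
    obs_path: str | Path,
    attrs_path: str | Path | None = None,
    climate_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
    horizon: tuple[int, int] = DEFAULT_HORIZON,
) -> SurveyPanel:
    """Read a survey panel from delimited-text (CSV) tables.

    Parameters
    ----------
    obs_path:
        CSV of long-format observations.  Required columns (after renaming
        through ``schema``): station_id, year, variable, value.  Optional:
        below_limit, reporting_limit, month.  A ``month`` column triggers
        survey-year attribution: January samples belong to the previous
        year's autumn; all other months keep their calendar year.
    attrs_path, climate_path:
        Optional CSVs of station attributes and annual climate series.
    schema:
        Mapping from canonical column names to the column names used in the
        files, e.g. ``{"station_id": "StationID"}``.
    horizon:
        Inclusive (first, last) admissible survey year.

    Raises
    ------
    SchemaError
        If a required column is absent.
    DuplicateRecordError
        If two rows share (station, year, variable).
    """
    rename = {v: k for k, v in (schema or {}).items()}
    obs = pd.read_csv(obs_path).rename(columns=rename)

    required = ["station_id", "year", "variable", "value"]
    missing = [c for c in required if c not in obs.columns]
    if missing:
        raise SchemaError(f"{obs_path}: missing required columns {missing}")

    month = obs["month"].to_numpy() if "month" in obs.columns else None
    obs["year"] = _attribute_year(obs["year"].to_numpy(), month)
    if "below_limit" not in obs.columns:
        obs["below_limit"] = False
    obs["below_limit"] = obs["below_limit"].fillna(False).astype(bool)
    if "reporting_limit" not in obs.columns:
        obs["reporting_limit"] = np.nan
    obs = obs[list(OBS_COLUMNS)]
    obs, diags = _validate_observations(obs, horizon)

    attrs = None
    if attrs_path is not None:
        attrs = pd.read_csv(attrs_path).rename(columns=rename)
        missing = [c for c in ATTR_COLUMNS if c not in attrs.columns]
        if missing:
            raise SchemaError(f"{attrs_path}: missing required columns {missing}")
        _validate_attributes(attrs)

    climate = None
    if climate_path is not None:
        climate = pd.read_csv(climate_path).rename(columns=rename)
        missing = [c for c in CLIMATE_COLUMNS if c not in climate.columns]
        if missing:
            raise SchemaError(f"{climate_path}: missing required columns {missing}")

    return SurveyPanel(observations=obs, attributes=attrs, climate=climate, diagnostics=diags)


def _validate_attributes(attrs: pd.DataFrame) -> None:
    lu_cols = [f"lu_{c}" for c in LANDUSE_CLASSES]
    lu = attrs[lu_cols].to_numpy(dtype=float)
    if (lu < 0).any():
        raise SchemaError("negative land-use percentage")
    sums = lu.sum(axis=1)
    bad = (sums < 99.0) | (sums > 101.0)
    if bad.any():
        ids = attrs.loc[bad, "station_id"].tolist()[:5]
        raise SchemaError(f"land-use percentages do not sum to ~100 for stations {ids}")
    if (attrs["catchment_area"].to_numpy(dtype=float) <= 0).any():
        raise SchemaError("non-positive catchment area")


def write_survey(panel: SurveyPanel, out_dir: str | Path, float_format: str = "%.10g") -> None:
    """Write a panel to ``obs.csv`` / ``attrs.csv`` / ``climate.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.observations.to_csv(out / "obs.csv", index=False, float_format=float_format)
    if panel.attributes is not None:
        panel.attributes.to_csv(out / "attrs.csv", index=False, float_format=float_format)
    if panel.climate is not None:
        panel.climate.to_csv(out / "climate.csv", index=False, float_format=float_format)


def substitute_below_limit(panel: SurveyPanel, policy: LimitPolicy | None = None) -> SurveyPanel:
    """Replace censored values with half the applicable reporting limit.

    Generic rule: a value flagged below its reporting limit becomes half that
    limit.  Cl dialect (active when ``policy.cl_max_limit`` is set): every Cl
    value at or below the historical maximum reporting limit -- censored or
    not -- becomes half that maximum, because the Cl limit changed over time
    and early low values are not comparable.

    The operation is idempotent: substituted values sit at half their limit,
    strictly below the limit itself, and the flags are cleared.

    Raises
    ------
    LimitPolicyError
        If a below-limit observation carries no reporting limit.
    """
    policy = policy or LimitPolicy()
    out = panel.copy()
    obs = out.observations
    flagged = obs["below_limit"].to_numpy(dtype=bool)
    limits = obs["reporting_limit"].to_numpy(dtype=float)
    if (flagged & np.isnan(limits)).any():
        rows = np.nonzero(flagged & np.isnan(limits))[0][:10].tolist()
        raise LimitPolicyError(f"below-limit rows without a reporting limit: {rows}")

    values = obs["value"].to_numpy(dtype=float)
    values[flagged] = 0.5 * limits[flagged]

    if policy.cl_max_limit is not None:
        is_cl = (obs["variable"] == "Cl").to_numpy()
        low = is_cl & (values <= policy.cl_max_limit)
        values[low] = 0.5 * policy.cl_max_limit

    obs["value"] = values
    obs["below_limit"] = False
    return out


def filter_stations(
    panel: SurveyPanel,
    trend_window: tuple[int, int] = (2012, 2023),
    response_variable: str = "pH",
    exclude: Iterable = (),
    min_obs: int = 2,
) -> tuple[SurveyPanel, dict]:
    """Keep stations with enough in-window response observations.

    Stations with fewer than ``min_obs`` observations of the response
    variable inside ``trend_window``, and any station named in ``exclude``,
    are removed entirely (all variables).  Returns the filtered panel and a
    retention report ``{"n_in", "n_retained", "n_removed_sparse",
    "n_removed_excluded"}``.

    Raises
    ------
    EmptyPanelError
        If no station survives.
    """
    lo, hi = trend_window
    if hi < lo:
        raise ValueError(f"empty trend window {trend_window}")
    obs = panel.observations
    exclude = set(exclude)

    resp = obs[
        (obs["variable"] == response_variable) & obs["year"].between(lo, hi)
    ]
    counts = resp.groupby("station_id").size()
    enough = set(counts.index[counts >= min_obs])
    all_stations = set(obs["station_id"])
    kept = (enough - exclude)

    if not kept:
        raise EmptyPanelError(
            f"no station has >= {min_obs} {response_variable} observations in "
            f"{trend_window} after exclusions"
        )

    out = panel.copy()
    out.observations = (
        obs[obs["station_id"].isin(kept)]
        .sort_values(["station_id", "variable", "year"])
        .reset_index(drop=True)
    )
    if out.attributes is not None:
        out.attributes = (
            out.attributes[out.attributes["station_id"].isin(kept)]
            .sort_values("station_id")
            .reset_index(drop=True)
        )
    if out.climate is not None:
        out.climate = (
            out.climate[out.climate["station_id"].isin(kept)]
            .sort_values(["station_id", "year"])
            .reset_index(drop=True)
        )

    report = {
        "n_in": len(all_stations),
        "n_retained": len(kept),
        "n_removed_sparse": len(all_stations - enough - exclude),
        "n_removed_excluded": len(all_stations & exclude),
    }
    return out, report
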