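"""Station-specific covariates and the centered trend response.

Raw panel data are condensed into one row per station holding three kinds
of covariates:

* **constant** -- catchment properties that do not change (clr-transformed
  land-use composition, catchment area, elevation, long-term climate mean);
* **initial** -- levels of chemistry and climate early in the record
  (2008-2013 by default), capturing where each lake started;
* **change** -- per-year rates of change over the trend window, from
  first/last differences for chemistry and Theil-Sen slopes for climate.

The response for the weighted trend regression is the station-wise
mean-centered series of the target variable (pH) inside the trend window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey_data import (
    CHEMISTRY_VARIABLES,
    LANDUSE_CLASSES,
    LOG10_VARIABLES,
    SurveyPanel,
)


class CovariateError(Exception):
    """Raised when a covariate cannot be constructed as specified."""


class TransformError(CovariateError):
    """A value transform hit a domain violation."""


# ---------------------------------------------------------------------------
# schema

@dataclass(frozen=True)
class CovariateSchema:
    """Declarative description of the covariate table.

    The default reproduces a 36-covariate layout with role counts
    8 change / 10 initial / 18 constant:

    * change (8): conductivity, Mg, Cl, Ca, Na, SO4 (first/last annual
      change on the log10 scale) + temperature and precipitation
      (Theil-Sen slopes of the annual series);
    * initial (10): all 8 chemistry variables (incl. pH and alkalinity)
      + temperature and precipitation window means;
    * constant (18): 15 clr land-use parts + catchment area + elevation
      + the overall precipitation mean.

    The enumerable constants (15 land-use + area + elevation + two overall
    climate means) would total 19; the default schema keeps the overall
    precipitation mean and folds the long-term temperature signal into its
    initial-window mean, which carries the same north-south gradient.
    Edit the schema (or load one from YAML) to choose differently.
    """

    change_chemistry: tuple[str, ...] = ("conductivity", "Mg", "Cl", "Ca", "Na", "SO4")
    change_climate: tuple[str, ...] = ("temperature", "precipitation")
    initial_chemistry: tuple[str, ...] = CHEMISTRY_VARIABLES
    initial_climate: tuple[str, ...] = ("temperature", "precipitation")
    landuse_classes: tuple[str, ...] = LANDUSE_CLASSES
    extra_constants: tuple[str, ...] = ("catchment_area", "elevation")
    overall_climate: tuple[str, ...] = ("precipitation",)
    initial_window: tuple[int, int] = (2008, 2013)
    initial_fallback_cutoff: int = 2018
    trend_window: tuple[int, int] = (2012, 2023)
    theil_sen_window: tuple[int, int] = (2012, 2020)
    overall_climate_span: tuple[int, int] = (1990, 2020)

    @property
    def change_names(self) -> tuple[str, ...]:
        return tuple(f"{v}_change" for v in self.change_chemistry + self.change_climate)

    @property
    def initial_names(self) -> tuple[str, ...]:
        return tuple(f"{v}_initial" for v in self.initial_chemistry + self.initial_climate)

    @property
    def constant_names(self) -> tuple[str, ...]:
        return (
            tuple(f"clr_{c}" for c in self.landuse_classes)
            + self.extra_constants
            + tuple(f"{v}_overall" for v in self.overall_climate)
        )

    def role_counts(self) -> dict[str, int]:
        return {
            "change": len(self.change_names),
            "initial": len(self.initial_names),
            "constant": len(self.constant_names),
        }

    def roles(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for n in self.change_names:
            out[n] = "change"
        for n in self.initial_names:
            out[n] = "initial"
        for n in self.constant_names:
            out[n] = "constant"
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in d:
                v = d[f]
                kwargs[f] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)


@dataclass
class CovariateTable:
    """Station x covariate matrix with per-covariate role labels.

    ``values`` is indexed by station_id; missing entries are NaN and are
    resolved downstream (the coordinates module), never imputed here.
    ``scale`` holds (mean, sd) per column once :func:`standardize` has run.
    """

    values: pd.DataFrame
    roles: dict[str, str]
    standardized: bool = False
    scale: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = set(self.values.columns) - set(self.roles)
        if unknown:
            raise CovariateError(f"covariates without a role: {sorted(unknown)}")

    @property
    def station_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class CenteredResponse:
    """Station-wise mean-centered response observations.

    ``data`` has columns station_id, year, value (centered); ``station_means``
    maps station_id to the in-window mean that was subtracted.  Within every
    station the centered values sum to zero.
    """

    data: pd.DataFrame
    station_means: pd.Series
    variable: str
    window: tuple[int, int]


# ---------------------------------------------------------------------------
# elementary transforms

def log10_chemistry(panel: SurveyPanel) -> SurveyPanel:
    """log10-transform every chemistry variable except pH, in place of the
    raw concentrations.  Must run after reporting-limit substitution so all
    values are positive.

    Raises
    ------
    TransformError
        Naming the offending station/year/variable on any non-positive value.
    """
    out = panel.copy()
    obs = out.observations
    mask = obs["variable"].isin(LOG10_VARIABLES).to_numpy()
    vals = obs["value"].to_numpy(dtype=float)
    bad = mask & ~np.isnan(vals) & (vals <= 0)
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        r = obs.iloc[i]
        raise TransformError(
            f"non-positive {r['variable']} at station {r['station_id']}, "
            f"year {int(r['year'])}: {r['value']}"
        )
    vals[mask] = np.log10(vals[mask])
    obs["value"] = vals
    return out


def clr(parts: Sequence[float], zero_policy: str = "half_min") -> np.ndarray:
    """Centered log-ratio transform of a composition.

    Closes ``parts`` to proportions, replaces zeros per ``zero_policy``
    ("half_min": half the smallest positive part, applied before closure),
    and returns ln(part / geometric mean).  The output sums to zero and is
    invariant to rescaling the input by a positive constant.

    Raises
    ------
    ValueError
        On negative parts or an all-zero composition.
    """
    x = np.asarray(parts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative compositional part")
    if not (x > 0).any():
        raise ValueError("all-zero composition")
    if (x == 0).any():
        if zero_policy != "half_min":
            raise ValueError(f"unknown zero policy {zero_policy!r}")
        x = x.copy()
        x[x == 0] = 0.5 * x[x > 0].min()
    p = x / x.sum()
    logp = np.log(p)
    return logp - logp.mean()


def initial_level(
    years: Sequence[int],
    values: Sequence[float],
    window: tuple[int, int] = (2008, 2013),
    fallback_cutoff: int = 2018,
) -> float:
    """Initial level of a sparsely observed series.

    Mean of the values observed inside ``window``; if none exist, the
    earliest later value observed strictly before ``fallback_cutoff``;
    otherwise NaN (missing is a legal outcome).
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    order = np.argsort(years, kind="stable")
    years, values = years[order], values[order]
    in_win = (years >= window[0]) & (years <= window[1])
    if in_win.any():
        return float(values[in_win].mean())
    later = (years > window[1]) & (years < fallback_cutoff)
    if later.any():
        return float(values[later][0])
    return float("nan")


def climate_summaries(
    years: Sequence[int],
    values: Sequence[float],
    window: tuple[int, int] = (2008, 2013),
) -> tuple[float, float]:
    """(window mean, full-span mean) of an annual climate series.

    The two summaries are kept as distinct covariates so a deviation of the
    initial window from the long-term mean remains identifiable.

    Raises
    ------
    CovariateError
        If the series does not cover the window contiguously.
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    order = np.argsort(years, kind="stable")
    years, values = years[order], values[order]
    wanted = set(range(window[0], window[1] + 1))
    if not wanted <= set(years.tolist()):
        raise CovariateError(f"climate series does not cover window {window}")
    in_win = (years >= window[0]) & (years <= window[1])
    return float(values[in_win].mean()), float(values.mean())


def annual_change(
    years: Sequence[int],
    values: Sequence[float],
    window: tuple[int, int] = (2012, 2023),
) -> float:
    """Average annual change (y_last - y_first) / (year_last - year_first)
    over the first and last observations inside ``window``.  Intermediate
    observations do not enter.

    Raises
    ------
    CovariateError
        With fewer than two in-window observations.
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    order = np.argsort(years, kind="stable")
    years, values = years[order], values[order]
    in_win = (years >= window[0]) & (years <= window[1])
    y, v = years[in_win], values[in_win]
    if len(y) < 2 or y[0] == y[-1]:
        raise CovariateError(
            f"annual change needs two observations at distinct years in {window}"
        )
    return float((v[-1] - v[0]) / (y[-1] - y[0]))


def theil_sen(
    years: Sequence[int],
    values: Sequence[float],
    window: tuple[int, int] = (2012, 2020),
) -> float:
    """Theil-Sen slope (median of all pairwise slopes) inside ``window``."""
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    in_win = (years >= window[0]) & (years <= window[1])
    y, v = years[in_win], values[in_win]
    if len(y) < 2:
        raise CovariateError(f"Theil-Sen needs two values in {window}")
    slope, _, _, _ = stats.theilslopes(v, y)
    return float(slope)


# ---------------------------------------------------------------------------
# table assembly

def _station_series(panel: SurveyPanel, variable: str) -> dict:
    """{station_id: (years, values)} for one variable."""
    sub = panel.variable(variable)
    out = {}
    for sid, grp in sub.groupby("station_id", sort=False):
        out[sid] = (grp["year"].to_numpy(), grp["value"].to_numpy(dtype=float))
    return out


def build_covariate_table(
    panel: SurveyPanel, schema: CovariateSchema | None = None
) -> CovariateTable:
    """Assemble the station x covariate matrix from a filtered, transformed
    panel.  Chemistry summaries are computed on whatever scale the panel
    carries (log10 after :func:`log10_chemistry`); missing initial levels
    are recorded as NaN, never imputed.

    Raises
    ------
    CovariateError
        If the schema references a variable absent from the panel, or the
        panel lacks attributes/climate tables.
    """
    schema = schema or CovariateSchema()
    if panel.attributes is None:
        raise CovariateError("panel has no station attributes")
    if panel.climate is None:
        raise CovariateError("panel has no climate series")

    present = set(panel.observations["variable"].unique())
    needed = set(schema.change_chemistry) | set(schema.initial_chemistry)
    absent = needed - present
    if absent:
        raise CovariateError(f"schema references absent variables: {sorted(absent)}")

    attrs = panel.attributes.set_index("station_id")
    stations = attrs.index.sort_values()
    rows = pd.DataFrame(index=stations, dtype=float)
    rows.index.name = "station_id"

    # change covariates: chemistry first/last differences
    for var in schema.change_chemistry:
        series = _station_series(panel, var)
        col = np.full(len(stations), np.nan)
        for i, sid in enumerate(stations):
            if sid in series:
                try:
                    col[i] = annual_change(*series[sid], window=schema.trend_window)
                except CovariateError:
                    pass
        rows[f"{var}_change"] = col

    # change covariates: climate Theil-Sen slopes
    climate = panel.climate.set_index("station_id")
    for var in schema.change_climate:
        col = np.full(len(stations), np.nan)
        for i, sid in enumerate(stations):
            grp = climate.loc[[sid]] if sid in climate.index else None
            if grp is not None and len(grp) >= 2:
                col[i] = theil_sen(
                    grp["year"].to_numpy(), grp[var].to_numpy(), window=schema.theil_sen_window
                )
        rows[f"{var}_change"] = col

    # initial levels: chemistry
    for var in schema.initial_chemistry:
        series = _station_series(panel, var)
        col = np.full(len(stations), np.nan)
        for i, sid in enumerate(stations):
            if sid in series:
                col[i] = initial_level(
                    *series[sid],
                    window=schema.initial_window,
                    fallback_cutoff=schema.initial_fallback_cutoff,
                )
        rows[f"{var}_initial"] = col

    # initial levels + overall means: climate
    span = schema.overall_climate_span
    for var in schema.initial_climate:
        init = np.full(len(stations), np.nan)
        overall = np.full(len(stations), np.nan)
        for i, sid in enumerate(stations):
            if sid not in climate.index:
                continue
            grp = climate.loc[[sid]]
            yr = grp["year"].to_numpy()
            val = grp[var].to_numpy(dtype=float)
            in_span = (yr >= span[0]) & (yr <= span[1])
            init[i], overall[i] = climate_summaries(
                yr[in_span], val[in_span], window=schema.initial_window
            )
        rows[f"{var}_initial"] = init
        if var in schema.overall_climate:
            rows[f"{var}_overall"] = overall

    # constants: clr land use, then scalar attributes
    lu_cols = [f"lu_{c}" for c in schema.landuse_classes]
    lu = attrs.loc[stations, lu_cols].to_numpy(dtype=float)
    clr_mat = np.vstack([clr(row) for row in lu])
    for j, c in enumerate(schema.landuse_classes):
        rows[f"clr_{c}"] = clr_mat[:, j]
    for name in schema.extra_constants:
        rows[name] = attrs.loc[stations, name].to_numpy(dtype=float)

    # order columns change -> initial -> constant
    ordered = list(schema.change_names) + list(schema.initial_names) + list(schema.constant_names)
    rows = rows[ordered]
    return CovariateTable(values=rows, roles=schema.roles())


def standardize(table: CovariateTable) -> CovariateTable:
    """Scale every covariate to mean 0, sample variance 1 (n-1 divisor),
    computed over non-missing entries.  Scaling parameters are retained in
    ``scale`` for back-transformation.

    Raises
    ------
    CovariateError
        Naming any column with zero variance or fewer than two distinct
        finite values.
    """
    vals = table.values
    means = vals.mean(axis=0, skipna=True)
    sds = vals.std(axis=0, ddof=1, skipna=True)
    bad = [c for c in vals.columns if not np.isfinite(sds[c]) or sds[c] == 0]
    if bad:
        raise CovariateError(f"zero-variance or degenerate covariates: {bad}")
    z = (vals - means) / sds
    scale = pd.DataFrame({"mean": means, "sd": sds})
    return CovariateTable(values=z, roles=dict(table.roles), standardized=True, scale=scale)


def center_response(
    panel: SurveyPanel,
    variable: str = "pH",
    window: tuple[int, int] = (2012, 2023),
) -> CenteredResponse:
    """Station-wise mean-center the response inside the trend window.

    Only in-window observations enter; each is reduced by its station's
    in-window mean, so per-station centered sums are exactly zero.
    """
    sub = panel.variable(variable)
    sub = sub[sub["year"].between(*window)].copy()
    means = sub.groupby("station_id")["value"].mean()
    sub["value"] = sub["value"].to_numpy() - means.loc[sub["station_id"]].to_numpy()
    data = sub[["station_id", "year", "value"]].reset_index(drop=True)
    return CenteredResponse(data=data, station_means=means, variable=variable, window=window)


def response_change(
    panel: SurveyPanel,
    variable: str = "pH",
    window: tuple[int, int] = (2012, 2023),
) -> pd.Series:
    """Per-station average annual change of the response (goal variable for
    the supervised coordinate system): (last - first) / (years between),
    using the first and last in-window observations on the native scale."""
    series = _station_series(panel, variable)
    out = {}
    for sid, (yr, val) in series.items():
        try:
            out[sid] = annual_change(yr, val, window=window)
        except CovariateError:
            out[sid] = np.nan
    s = pd.Series(out, name=f"{variable}_change").sort_index()
    s.index.name = "station_id"
    return s
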