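"""Locally weighted trend regression on an arbitrary coordinate system.

This is the engine shared by geographically weighted regression (GWR, when
the coordinates are projected easting/northing) and thematically weighted
regression (TWR, when they are PCA or PLS scores of driver covariates).
For every station a weighted least-squares regression of the centered
response on time is fitted inside an adaptive window:

* the window is the k nearest observation rows in Euclidean coordinate
  distance (adaptive knn bandwidth: the window radius b is the distance to
  the k-th nearest row, so windows shrink where stations are dense);
* weights follow the bi-square kernel w = (1 - (d/b)^2)^2 for d < b and 0
  beyond;
* k is chosen by leave-one-out cross-validation over a grid.

Observation rows, not stations, define neighborhoods: a station's multiple
visits share its coordinates and enter its own window at distance zero.

Time coding.  The response is station-wise mean centered, which removes the
between-station level but leaves each station's points on a line whose
intercept depends on the station's mean visit year.  Pairing the centering
with station-wise centered time (t_i minus the station's mean in-window
year, the classical within transformation) makes the local regression an
exact weighted average of within-station slopes; coding time against the
global window midpoint is available as an option but attenuates slopes
when visit panels mix.  The default is station-centered time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coordinates import ThematicCoordinates
from .covariates import CenteredResponse


class TwrError(Exception):
    pass


class DegenerateWindowError(TwrError):
    """No bandwidth on the grid yields a usable window."""


#: Minimum k below which a time-trend window cannot be identified
#: (p predictors + intercept + 1).
def min_k(n_predictors: int = 1) -> int:
    return n_predictors + 2


@dataclass(frozen=True)
class KernelSpec:
    """Bi-square kernel with an adaptive k-nearest-neighbour bandwidth."""

    k: int
    kind: str = "bisquare"

    def __post_init__(self) -> None:
        if self.kind != "bisquare":
            raise TwrError(f"unsupported kernel {self.kind!r}")
        if self.k < min_k():
            raise TwrError(f"k={self.k} below the identifiable minimum {min_k()}")


@dataclass
class TrendDesign:
    """Observation rows ready for local fitting.

    ``rows`` has columns station_id, year, y (centered response) and t (the
    coded time); ``row_coords`` holds each row's position (n_rows x m) and
    ``station_coords`` one position per station (n_stations x m, indexed by
    station_id).
    """

    rows: pd.DataFrame
    row_coords: np.ndarray
    station_coords: pd.DataFrame
    source: str
    time_coding: str

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class TrendSurface:
    """Per-station local fits plus the bandwidth-selection trace.

    ``table`` columns: station_id (index), coordinate columns, slope_per_year,
    intercept, local_r2, bandwidth_distance, n_eff, flag ("ok" or
    "degenerate").
    """

    table: pd.DataFrame
    source: str
    k: int
    cv_trace: pd.DataFrame | None = None


def bisquare_weight(d, b: float):
    """Bi-square kernel weight (1 - (d/b)^2)^2 for d < b, else 0.

    Continuous, equal to 1 at d = 0 and 0 from d = b outward, and invariant
    under joint rescaling of d and b.

    Raises
    ------
    TwrError
        If b <= 0.
    """
    if b <= 0:
        raise TwrError(f"bandwidth must be positive, got {b}")
    d = np.asarray(d, dtype=float)
    u = d / b
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(w) if w.ndim == 0 else w


def adaptive_bandwidth(coords: np.ndarray, target: int, k: int) -> float:
    """Distance from row ``target`` to its k-th nearest row, self included
    (the self-distance is 0, and co-located rows from the same station also
    contribute distance 0).

    Raises
    ------
    TwrError
        If k exceeds the number of rows.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if not 1 <= k <= n:
        raise TwrError(f"k={k} outside [1, {n}]")
    d = np.linalg.norm(coords - coords[target], axis=1)
    return float(np.sort(d)[k - 1])


def build_design(
    coords: ThematicCoordinates,
    response: CenteredResponse,
    time_coding: str = "station_mean",
) -> TrendDesign:
    """Join response rows to station coordinates and code time.

    ``time_coding``: "station_mean" (default) codes each row's year against
    its station's mean in-window visit year; "window_midpoint" codes against
    the midpoint of the trend window.  Stations without coordinates (e.g.
    dropped by complete-case screening) are left out with their rows.
    """
    if time_coding not in ("station_mean", "window_midpoint"):
        raise TwrError(f"unknown time coding {time_coding!r}")
    sc = coords.coords
    rows = response.data[response.data["station_id"].isin(sc.index)].copy()
    rows = rows.sort_values(["station_id", "year"]).reset_index(drop=True)
    rows = rows.rename(columns={"value": "y"})
    if time_coding == "station_mean":
        mean_year = rows.groupby("station_id")["year"].transform("mean")
        rows["t"] = rows["year"] - mean_year
    else:
        lo, hi = response.window
        rows["t"] = rows["year"] - (lo + hi) / 2.0
    row_coords = sc.loc[rows["station_id"]].to_numpy(dtype=float)
    station_coords = sc.loc[sc.index.isin(rows["station_id"].unique())].sort_index()
    return TrendDesign(
        rows=rows,
        row_coords=row_coords,
        station_coords=station_coords,
        source=coords.source,
        time_coding=time_coding,
    )


# ---------------------------------------------------------------------------
# weighted simple regression, vectorized over targets

def _wls_line(W: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Weighted least squares of y on [1, t] for many weight rows at once.

    W is (n_targets x n_rows); returns per-target slope, intercept,
    local R^2, sum of weights, and a degeneracy mask (fewer than two
    distinct times with positive weight).
    """
    Sw = W.sum(axis=1)
    St = W @ t
    Stt = W @ (t * t)
    Sy = W @ y
    Sty = W @ (t * y)
    Syy = W @ (y * y)
    det = Sw * Stt - St**2

    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (Sw * Sty - St * Sy) / det
        intercept = (Stt * Sy - St * Sty) / det
        # weighted SSE via the closed form sum w y^2 - a*Sy - b*Sty
        sse = Syy - intercept * Sy - slope * Sty
        sst = Syy - Sy**2 / Sw
        r2 = 1.0 - sse / sst

    # degenerate when the weighted time variance is (numerically) zero
    scale = Sw * Stt + St**2 + 1e-300
    degenerate = ~(det / scale > 1e-12) | (Sw <= 0)
    # constant response in the window: define R^2 = 0 rather than 0/0
    flat = sst <= 1e-300
    r2 = np.where(flat & ~degenerate, 0.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    return slope, intercept, r2, Sw, degenerate


def _weight_matrix(
    targets: np.ndarray, row_coords: np.ndarray, k: int, exclude_diag: bool = False
) -> np.ndarray:
    """Bi-square weights of every observation row for every target point.

    Bandwidth per target: distance to its k-th nearest row (after removing
    the held-out row itself when ``exclude_diag``).  Rows at exactly the
    bandwidth distance receive weight zero, so tied k-th distances are
    harmless.
    """
    d = np.sqrt(
        np.maximum(
            ((targets[:, None, :] - row_coords[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )
    if exclude_diag:
        np.fill_diagonal(d, np.inf)
    b = np.partition(d, k - 1, axis=1)[:, k - 1]
    if (b <= 0).any():
        raise TwrError(
            f"k={k} gives a zero bandwidth for {(b <= 0).sum()} targets "
            "(co-located rows); increase k"
        )
    with np.errstate(invalid="ignore"):
        u = d / b[:, None]
    W = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    if exclude_diag:
        np.fill_diagonal(W, 0.0)
    return W


def local_fit(design: TrendDesign, station_id, kernel: KernelSpec) -> dict:
    """Local weighted trend fit at one station's coordinates.

    Returns a dict with slope_per_year, intercept, local_r2,
    bandwidth_distance, n_eff and flag; a window without two distinct
    positively weighted times yields NaN estimates flagged "degenerate".
    """
    target = design.station_coords.loc[[station_id]].to_numpy(dtype=float)
    t = design.rows["t"].to_numpy(dtype=float)
    y = design.rows["y"].to_numpy(dtype=float)
    d = np.linalg.norm(design.row_coords - target, axis=1)
    b = float(np.sort(d)[kernel.k - 1])
    if b <= 0:
        raise TwrError(f"k={kernel.k} gives a zero bandwidth at {station_id}")
    W = bisquare_weight(d, b)[None, :]
    slope, intercept, r2, sw, degen = _wls_line(W, t, y)
    bad = bool(degen[0])
    return {
        "station_id": station_id,
        "slope_per_year": np.nan if bad else float(slope[0]),
        "intercept": np.nan if bad else float(intercept[0]),
        "local_r2": np.nan if bad else float(r2[0]),
        "bandwidth_distance": b,
        "n_eff": float(sw[0]),
        "flag": "degenerate" if bad else "ok",
    }


def default_k_grid(n_rows: int, n_predictors: int = 1, size: int = 12) -> list[int]:
    """Geometrically spaced candidate neighbourhood sizes between
    max(10, p + 2) and n."""
    lo = max(10, min_k(n_predictors))
    hi = n_rows
    if hi < lo:
        raise TwrError(f"too few rows ({n_rows}) for a bandwidth grid")
    grid = np.unique(
        np.round(np.geomspace(lo, hi, num=size)).astype(int)
    )
    return [int(k) for k in grid]


def cv_bandwidth(
    design: TrendDesign,
    k_grid: list[int] | None = None,
    cv_unit: str = "observation",
) -> tuple[int, pd.DataFrame]:
    """Leave-one-out cross-validation of the neighbourhood size.

    For every k on the grid, each held-out unit is predicted from a local
    fit at its own coordinates computed without it, and the raw held-out
    squared errors are summed.  ``cv_unit`` "observation" holds out single
    rows; "station" holds out all of a station's rows together (the
    response centering uses within-station information, so observation-level
    CV carries a mild leakage; station-level CV avoids it at higher cost).
    Returns the score-minimizing k (smallest on ties) and the full trace.

    Raises
    ------
    DegenerateWindowError
        If every k on the grid leaves some target without a usable window.
    """
    if cv_unit not in ("observation", "station"):
        raise TwrError(f"unknown cv unit {cv_unit!r}")
    t = design.rows["t"].to_numpy(dtype=float)
    y = design.rows["y"].to_numpy(dtype=float)
    n = design.n_rows
    if k_grid is None:
        k_grid = default_k_grid(n)
    if any(k > n for k in k_grid):
        raise TwrError(f"grid contains k above n={n}")

    if cv_unit == "station":
        groups = design.rows["station_id"].to_numpy()
    scores = []
    for k in k_grid:
        try:
            if cv_unit == "observation":
                W = _weight_matrix(design.row_coords, design.row_coords, k, exclude_diag=True)
            else:
                W = _weight_matrix_station_cv(design.row_coords, groups, k)
        except TwrError:
            scores.append(np.inf)
            continue
        slope, intercept, _, _, degen = _wls_line(W, t, y)
        if degen.any():
            scores.append(np.inf)
            continue
        pred = intercept + slope * t
        scores.append(float(((y - pred) ** 2).sum()))

    trace = pd.DataFrame({"k": k_grid, "cv_score": scores})
    if not np.isfinite(trace["cv_score"]).any():
        raise DegenerateWindowError("every k on the grid is degenerate")
    # ties break toward less smoothing: smallest k among minimal scores
    best = trace["cv_score"].min()
    k_star = int(trace.loc[trace["cv_score"] == best, "k"].min())
    return k_star, trace


def _weight_matrix_station_cv(
    row_coords: np.ndarray, groups: np.ndarray, k: int
) -> np.ndarray:
    """Station-level leave-out weights: row i's window excludes every row of
    its own station; the bandwidth is the k-th nearest remaining row."""
    d = np.sqrt(
        np.maximum(
            ((row_coords[:, None, :] - row_coords[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )
    same = groups[:, None] == groups[None, :]
    d[same] = np.inf
    b = np.partition(d, k - 1, axis=1)[:, k - 1]
    if not np.isfinite(b).all() or (b <= 0).any():
        raise TwrError(f"k={k} gives no usable bandwidth under station-level CV")
    u = d / b[:, None]
    with np.errstate(invalid="ignore"):
        W = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return W


def fit_trend_surface(
    design: TrendDesign,
    k: int | None = None,
    k_grid: list[int] | None = None,
    cv_unit: str = "observation",
) -> TrendSurface:
    """One local trend fit per station at the station's own coordinates.

    If ``k`` is None the neighbourhood size is chosen by
    :func:`cv_bandwidth` first.  Degenerate windows yield NaN estimates
    flagged per station without aborting the surface.
    """
    trace = None
    if k is None:
        k, trace = cv_bandwidth(design, k_grid=k_grid, cv_unit=cv_unit)
    if not min_k() <= k <= design.n_rows:
        raise TwrError(f"k={k} outside [{min_k()}, {design.n_rows}]")

    t = design.rows["t"].to_numpy(dtype=float)
    y = design.rows["y"].to_numpy(dtype=float)
    targets = design.station_coords.to_numpy(dtype=float)
    d = np.sqrt(
        np.maximum(
            ((targets[:, None, :] - design.row_coords[None, :, :]) ** 2).sum(axis=2),
            0.0,
        )
    )
    b = np.partition(d, k - 1, axis=1)[:, k - 1]
    if (b <= 0).any():
        raise TwrError(f"k={k} gives a zero bandwidth for some stations")
    u = d / b[:, None]
    W = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    slope, intercept, r2, sw, degen = _wls_line(W, t, y)

    table = design.station_coords.copy()
    table["slope_per_year"] = np.where(degen, np.nan, slope)
    table["intercept"] = np.where(degen, np.nan, intercept)
    table["local_r2"] = np.where(degen, np.nan, r2)
    table["bandwidth_distance"] = b
    table["n_eff"] = sw
    table["flag"] = np.where(degen, "degenerate", "ok")
    return TrendSurface(table=table, source=design.source, k=k, cv_trace=trace)
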