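"""Thematic coordinate systems from PCA or single-response PLS.

The weighted trend regression needs a coordinate system in which "nearby"
stations are similar.  Geography is one choice; this module builds the
alternative: scores of the stations on components extracted from the
standardized covariate table, either unsupervised (PCA) or supervised by a
per-station trend proxy (PLS1 via NIPALS).  The raw scores -- not rescaled
to unit variance -- serve as coordinates, so the first component spans a
wider numeric range than later ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateTable


class CoordinateError(Exception):
    pass


class RankError(CoordinateError):
    """The data cannot support another component."""


@dataclass
class PcaModel:
    """Principal components of the standardized covariate matrix.

    ``loadings`` is covariates x components (orthonormal columns);
    ``scores`` is stations x components; ``explained_variance_pct[c]`` is
    the c-th eigenvalue of the correlation matrix as a percentage of the
    number of covariates.  Score column variances (n-1 divisor) equal the
    eigenvalues.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_pct: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PlsModel:
    """NIPALS PLS1 decomposition against a single goal variable.

    Weight vectors ``weights`` (unit norm, covariates x components),
    x-loadings ``x_loadings``, y-loadings ``y_loadings`` (per component),
    scores ``scores`` (stations x components, mutually orthogonal), and the
    percentage of the standardized goal variable's variance explained per
    component.
    """

    weights: pd.DataFrame
    x_loadings: pd.DataFrame
    y_loadings: np.ndarray
    scores: pd.DataFrame
    response_variance_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class ThematicCoordinates:
    """Station positions used for distance weighting.

    ``coords`` is stations x m (typically m = 2); ``source`` records where
    the axes came from, e.g. ``"pca:1,2"``, ``"pls:1,2"`` or
    ``"geographic"``.
    """

    coords: pd.DataFrame
    source: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords.to_numpy(dtype=float)).all():
            raise CoordinateError("non-finite coordinate entries")

    @property
    def station_ids(self) -> pd.Index:
        return self.coords.index

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------

def resolve_missing(table: CovariateTable, policy: str = "complete_case") -> pd.DataFrame:
    """Resolve NaN covariate entries before component extraction.

    ``complete_case`` drops every station with any missing covariate;
    ``mean_impute`` fills with the column mean (0 on the standardized
    scale).

    Raises
    ------
    CoordinateError
        If complete-case leaves fewer than 3 stations, or on an unknown
        policy.
    """
    vals = table.values
    if policy == "complete_case":
        out = vals.dropna(axis=0, how="any")
        if len(out) < 3:
            raise CoordinateError(
                f"complete-case screening leaves {len(out)} stations (< 3)"
            )
        return out
    if policy == "mean_impute":
        return vals.fillna(vals.mean(axis=0))
    raise CoordinateError(f"unknown missingness policy {policy!r}")


def _orient(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: flip each component so its
    largest-magnitude loading is positive."""
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]
    return loadings, scores


def fit_pca(Z: pd.DataFrame, n_components: int = 4) -> PcaModel:
    """PCA of a standardized covariate matrix via SVD.

    Equivalent to an eigendecomposition of the correlation matrix: loadings
    are the eigenvectors, eigenvalues are squared singular values / (n-1),
    and explained percentages are eigenvalue / p x 100.  Columns of ``Z``
    must already be standardized (mean 0, sample variance 1).

    Raises
    ------
    CoordinateError
        With fewer than 2 stations or more components than rank allows.
    """
    X = Z.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise CoordinateError("PCA needs at least 2 stations")
    if n_components > min(n - 1, p):
        raise CoordinateError(f"cannot extract {n_components} components from {n}x{p}")
    # columns are standardized, but guard against drift in the column means
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    load = Vt.T[:, :n_components]
    scores = X @ load
    load, scores = _orient(load, scores)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    return PcaModel(
        loadings=pd.DataFrame(load, index=Z.columns, columns=comp),
        scores=pd.DataFrame(scores, index=Z.index, columns=comp),
        explained_variance_pct=eig[:n_components] / p * 100.0,
        eigenvalues=eig[:n_components],
    )


def fit_pls1(Z: pd.DataFrame, g: pd.Series, n_components: int = 2) -> PlsModel:
    """NIPALS PLS1 of standardized covariates against a single goal variable.

    The goal variable (e.g. per-station annual pH change) is standardized
    internally.  Per component c, with X_c, y_c the deflated matrices:

        w_c = X_c' y_c / ||X_c' y_c||      (unit weight vector)
        t_c = X_c w_c                      (scores)
        p_c = X_c' t_c / (t_c' t_c)        (x-loadings)
        q_c = y_c' t_c / (t_c' t_c)        (y-loading)
        X_{c+1} = X_c - t_c p_c',  y_{c+1} = y_c - t_c q_c

    Score vectors are mutually orthogonal.  The reported response-variance
    percentages are q_c^2 t_c't_c / y'y on the standardized scale.

    Raises
    ------
    RankError
        If X'y vanishes at any stage (no covariance left to model).
    CoordinateError
        If ``g`` is not aligned with ``Z`` or contains non-finite values.
    """
    if not Z.index.equals(g.index):
        g = g.reindex(Z.index)
    y = g.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise CoordinateError("goal variable has missing or non-finite entries")
    X = Z.to_numpy(dtype=float).copy()
    n, p = X.shape
    y = (y - y.mean()) / y.std(ddof=1)
    ss_y = float(y @ y)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    share = np.zeros(n_components)
    yc = y.copy()
    for c in range(n_components):
        xy = X.T @ yc
        norm = np.linalg.norm(xy)
        if norm < 1e-12:
            raise RankError(f"X'y vanished at component {c + 1}")
        w = xy / norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise RankError(f"degenerate score vector at component {c + 1}")
        pvec = X.T @ t / tt
        q = float(yc @ t) / tt
        W[:, c], T[:, c], P[:, c], Q[c] = w, t, pvec, q
        share[c] = q**2 * tt / ss_y * 100.0
        X = X - np.outer(t, pvec)
        yc = yc - t * q

    Wo, To = _orient(W.copy(), T.copy())
    flip = np.sign((Wo * W).sum(axis=0))  # +-1 per component
    P = P * flip
    Q = Q * flip
    comp = [f"PLS{i + 1}" for i in range(n_components)]
    return PlsModel(
        weights=pd.DataFrame(Wo, index=Z.columns, columns=comp),
        x_loadings=pd.DataFrame(P, index=Z.columns, columns=comp),
        y_loadings=Q,
        scores=pd.DataFrame(To, index=Z.index, columns=comp),
        response_variance_pct=share,
    )


def extract_coordinates(
    model: PcaModel | PlsModel, which: tuple[int, int] = (1, 2)
) -> ThematicCoordinates:
    """Raw score columns for the requested (1-based) components, in the
    requested order, tagged with the model type and indices.

    Raises
    ------
    CoordinateError
        On an out-of-range component index.
    """
    tag = "pca" if isinstance(model, PcaModel) else "pls"
    for c in which:
        if not 1 <= c <= model.n_components:
            raise CoordinateError(
                f"component {c} out of range (model has {model.n_components})"
            )
    cols = [model.scores.columns[c - 1] for c in which]
    coords = model.scores[cols].copy()
    return ThematicCoordinates(coords=coords, source=f"{tag}:{','.join(map(str, which))}")


def geographic_coordinates(attributes: pd.DataFrame) -> ThematicCoordinates:
    """Projected easting/northing as the coordinate system -- the classic
    geographically weighted special case of the same engine."""
    coords = attributes.set_index("station_id")[["easting", "northing"]].astype(float)
    coords = coords.sort_index()
    return ThematicCoordinates(coords=coords, source="geographic")
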