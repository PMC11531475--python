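"""Boundary-determinant predictors and the autologistic boundary model.

Predictors are neighborhood statistics of the landscape: coefficients of
variation of the four climate fields over each cell's 3x3 neighborhood,
mean absolute elevation difference to the 8 neighbors, the standard
deviation over time of focal-to-neighbor drift distances, and the raw past
climate velocity.  The response is boundary membership inside a metric
buffer around the boundary band.  The model is a logistic GLM with a
row-standardized within-radius autocovariate absorbing residual spatial
autocorrelation; effect sizes are Fisher's z of the coefficient t-values,
with bootstrap CIs over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .boundaries import BoundaryMap, distance_to_boundary
from .community import Grid
from .exceptions import (
    DegenerateResponseError,
    InvalidArgumentError,
)
from .synth import Landscape

__all__ = [
    "PredictorTable",
    "BoundaryModelFit",
    "neighborhood_cv",
    "altitude_variation",
    "tectonic_sd",
    "vif",
    "boundary_response",
    "build_predictors",
    "fit_boundary_model",
    "fisher_z",
]

_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _neighbor_stack(values: np.ndarray, grid: Grid) -> np.ndarray:
    """(n_cells, 8) neighbor values, NaN where the neighbor falls off-grid."""
    img = np.asarray(values, float).reshape(grid.ny, grid.nx)
    pad = np.pad(img, 1, constant_values=np.nan)
    stack = np.stack([
        pad[1 + dr:grid.ny + 1 + dr, 1 + dc:grid.nx + 1 + dc].reshape(-1)
        for dr, dc in _OFFSETS
    ], axis=1)
    return stack


def neighborhood_cv(values: np.ndarray, grid: Grid) -> np.ndarray:
    """CV (sample SD over |mean|) of the focal cell plus its queen neighbors.

    Edge cells use whatever neighbors exist.  Neighborhoods whose mean is
    (numerically) zero are flagged NaN — CV is undefined there.
    """
    values = np.asarray(values, float)
    if values.shape != (grid.n_cells,):
        raise InvalidArgumentError("field must cover every grid cell")
    block = np.column_stack([values, _neighbor_stack(values, grid)])
    mean = np.nanmean(block, axis=1)
    sd = np.nanstd(block, axis=1, ddof=1)
    scale = np.nanmax(np.abs(block)) or 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(mean) > 1e-12 * scale, sd / np.abs(mean), np.nan)
    return out


def altitude_variation(elevation: np.ndarray, grid: Grid) -> np.ndarray:
    """Mean absolute elevation difference between focal cell and its neighbors."""
    elevation = np.asarray(elevation, float)
    if elevation.shape != (grid.n_cells,):
        raise InvalidArgumentError("elevation must cover every grid cell")
    neigh = _neighbor_stack(elevation, grid)
    return np.nanmean(np.abs(neigh - elevation[:, None]), axis=1)


def tectonic_sd(trajectories: np.ndarray, grid: Grid) -> np.ndarray:
    """Temporal SD of focal-to-neighbor drift distances, averaged over neighbors.

    For each focal cell and each queen neighbor the Euclidean distance
    between their drifting positions is tracked over all timesteps; the SD
    of that distance series measures how much the pair's separation changed.
    Rigid common motion of all cells therefore scores exactly zero.  The
    per-neighbor SDs are averaged into one value per cell.
    """
    traj = np.asarray(trajectories, float)
    if traj.ndim != 3 or traj.shape[0] != grid.n_cells or traj.shape[2] != 2:
        raise InvalidArgumentError("trajectories must be (n_cells, T, 2)")
    if traj.shape[1] < 2:
        raise InvalidArgumentError("need T >= 2 timesteps")
    img_ids = np.arange(grid.n_cells).reshape(grid.ny, grid.nx)
    pad = np.pad(img_ids, 1, constant_values=-1)
    out = np.zeros(grid.n_cells)
    counts = np.zeros(grid.n_cells)
    for dr, dc in _OFFSETS:
        nb = pad[1 + dr:grid.ny + 1 + dr, 1 + dc:grid.nx + 1 + dc].reshape(-1)
        valid = nb >= 0
        focal = np.flatnonzero(valid)
        dist = np.linalg.norm(traj[focal] - traj[nb[valid]], axis=2)  # (m, T)
        out[focal] += dist.std(axis=1, ddof=1)
        counts[focal] += 1
    return out / np.maximum(counts, 1)


@dataclass
class PredictorTable:
    """Per-cell predictor columns with an inclusion mask."""

    data: pd.DataFrame  # indexed by cell_id
    standardized: bool = False

    PREDICTORS = ["temp_het", "tempseas_het", "precip_het", "precipseas_het",
                  "altitude_var", "tectonic_sd", "past_velocity"]

    def included(self) -> np.ndarray:
        """Cell ids with no missing predictor values."""
        return self.data.index.to_numpy()[~self.data.isna().any(axis=1).to_numpy()]

    def matrix(self, cells: np.ndarray) -> np.ndarray:
        return self.data.loc[cells, self.columns].to_numpy(float)

    @property
    def columns(self) -> list[str]:
        return [c for c in self.PREDICTORS if c in self.data.columns]

    def standardize(self) -> "PredictorTable":
        """Mean-0 / variance-1 columns over cells with complete data (idempotent)."""
        keep = ~self.data.isna().any(axis=1)
        df = self.data.loc[keep].copy()
        for c in self.columns:
            col = df[c].to_numpy(float)
            sd = col.std(ddof=0)
            if sd == 0:
                raise InvalidArgumentError(f"predictor {c!r} is constant")
            df[c] = (col - col.mean()) / sd
        return PredictorTable(data=df, standardized=True)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index_label="cell_id")


def build_predictors(land: Landscape) -> PredictorTable:
    """Assemble the standard predictor set from a landscape."""
    grid = land.grid
    df = pd.DataFrame({
        "temp_het": neighborhood_cv(land.temp_mean, grid),
        "tempseas_het": neighborhood_cv(land.temp_seasonality, grid),
        "precip_het": neighborhood_cv(land.precip_mean, grid),
        "precipseas_het": neighborhood_cv(land.precip_seasonality, grid),
        "altitude_var": altitude_variation(land.elevation, grid),
        "tectonic_sd": tectonic_sd(land.drift_trajectories, grid),
        "past_velocity": np.asarray(land.past_velocity, float),
    }, index=pd.Index(np.arange(grid.n_cells), name="cell_id"))
    return PredictorTable(data=df)


def vif(p: PredictorTable) -> pd.Series:
    """Variance inflation factor 1/(1 - R2_j) per predictor; inf if collinear."""
    cells = p.included()
    x = p.matrix(cells)
    if x.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 predictors")
    out = {}
    for j, name in enumerate(p.columns):
        yj = x[:, j]
        others = np.delete(x, j, axis=1)
        if yj.std() == 0:
            raise InvalidArgumentError(f"predictor {name!r} is constant")
        design = np.column_stack([np.ones(len(yj)), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def boundary_response(b: BoundaryMap, buffer_km: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Binary YES/NO response inside the boundary buffer.

    YES (1) = boundary cells; NO (0) = cells within ``buffer_km`` of the
    boundary but not on it; cells beyond the buffer are excluded.  Returns
    ``(response, mask)`` over all grid cells; response is only meaningful
    where ``mask`` is True.
    """
    if b.n_boundary_cells == 0:
        raise DegenerateResponseError("empty boundary")
    if b.distance is None:
        b = distance_to_boundary(b)
    mask = b.distance <= buffer_km
    response = b.boundary.astype(int)
    if not np.any(mask & ~b.boundary):
        raise DegenerateResponseError("boundary fills its buffer: no NO cells")
    return response, mask


def fisher_z(t_value: float, df: int) -> tuple[float, float]:
    """Fisher's z effect size (and its SE) from a t statistic.

    ``r = sign(t) * sqrt(t^2 / (t^2 + df))``, ``z = atanh(r)``,
    ``se = 1 / sqrt(n - 3)`` with ``n = df + 2``.
    """
    if df < 3:
        raise InvalidArgumentError("df must be >= 3")
    r = np.sign(t_value) * np.sqrt(t_value**2 / (t_value**2 + df))
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = float(np.arctanh(r))
    se = float(1.0 / np.sqrt(df - 1))  # n - 3 = (df + 2) - 3
    return z, se


@dataclass
class BoundaryModelFit:
    """Autologistic fit: per-predictor coefficients and Fisher-z effect sizes."""

    terms: pd.DataFrame  # coefficient, t_value, fisher_z, z_ci_low, z_ci_high, significant
    n_obs: int
    n_boot: int
    neighborhood_radius_km: float
    converged: bool = True
    warnings: list = field(default_factory=list)

    def write_csv(self, path) -> None:
        self.terms.to_csv(path, index_label="term")


def _autocovariate(response: np.ndarray, cells: np.ndarray, grid: Grid,
                   radius_km: float) -> np.ndarray:
    """Row-standardized mean of neighbor responses within a metric radius."""
    coords = grid.centroids(cells)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius_km, output_type="ndarray")
    n = len(cells)
    sums = np.zeros(n)
    counts = np.zeros(n)
    if len(pairs):
        np.add.at(sums, pairs[:, 0], response[pairs[:, 1]])
        np.add.at(sums, pairs[:, 1], response[pairs[:, 0]])
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _irls(y: np.ndarray, x: np.ndarray, alpha: float, max_iter: int = 60,
          tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS logistic fit with optional L2 penalty (intercept unpenalized)."""
    p = x.shape[1]
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    info = np.eye(p)
    ok = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = x.T @ (y - mu) - pen @ beta
        info = x.T @ (x * w[:, None]) + pen
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            ok = True
            break
    return beta, info, ok


def _fit_logit(endog: np.ndarray, exog: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logit; ridge-penalized fallback under separation."""
    beta, info, ok = _irls(endog, exog, alpha=0.0)
    clean = ok and np.max(np.abs(beta)) < 15.0  # huge |beta| on standardized X ~ separation
    if not clean:
        beta, info, _ = _irls(endog, exog, alpha=1e-2)
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return beta, beta / bse, clean


def fit_boundary_model(
    response: np.ndarray,
    mask: np.ndarray,
    predictors: PredictorTable,
    grid: Grid,
    radius_km: float = 283.0,
    n_boot: int = 200,
    seed: int = 0,
) -> BoundaryModelFit:
    """Logistic regression of boundary membership on standardized predictors.

    The design adds an autocovariate (row-standardized mean of neighbor
    responses within ``radius_km``) to absorb spatial autocorrelation.
    Bootstrap CIs (percentile, over resampled cells) are reported on the
    Fisher-z scale; a predictor is significant when its z CI excludes 0.
    """
    warnings_: list[str] = []
    if not predictors.standardized:
        predictors = predictors.standardize()
    v = vif(predictors)
    if (v >= 2).any():
        warnings_.append(f"VIF >= 2 for: {list(v[v >= 2].index)}")
    cells = np.intersect1d(np.flatnonzero(mask), predictors.included())
    y = np.asarray(response)[cells].astype(float)
    if len(np.unique(y)) < 2:
        raise DegenerateResponseError("response has a single class on included cells")
    x = predictors.matrix(cells)
    auto = _autocovariate(y, cells, grid, radius_km)
    names = predictors.columns + ["autocovariate"]
    exog = np.column_stack([np.ones(len(y)), x, auto])
    df_resid = len(y) - exog.shape[1]
    if df_resid < 3:
        raise InvalidArgumentError("too few observations for the model")

    params, tvals, converged = _fit_logit(y, exog)
    if not converged:
        warnings_.append("separation or non-convergence: penalized fallback used")
    point = {name: (params[i + 1], tvals[i + 1]) for i, name in enumerate(names)}

    rng = np.random.default_rng(seed)
    boot_z = np.full((n_boot, len(names)), np.nan)
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            continue
        exb = exog[idx]
        _, tb, _ = _fit_logit(yb, exb)
        dfb = n - exog.shape[1]
        boot_z[b] = [fisher_z(tb[i + 1], dfb)[0] for i in range(len(names))]

    rows = []
    for i, name in enumerate(names):
        coef, t = point[name]
        z, _ = fisher_z(t, df_resid)
        col = boot_z[:, i]
        col = col[np.isfinite(col)]
        if len(col) == 0:
            lo = hi = z
        else:
            lo, hi = np.percentile(col, [2.5, 97.5])
            lo, hi = min(lo, z), max(hi, z)
        rows.append({"coefficient": float(coef), "t_value": float(t),
                     "fisher_z": z, "z_ci_low": float(lo), "z_ci_high": float(hi),
                     "significant": bool(lo > 0 or hi < 0)})
    terms = pd.DataFrame(rows, index=names)
    return BoundaryModelFit(terms=terms, n_obs=len(y), n_boot=n_boot,
                            neighborhood_radius_km=radius_km,
                            converged=converged, warnings=warnings_)
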