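"""Liebig limiting-factor hindcast of population density over climate cubes.

For each 500-year time step the fitted quantile ensembles are projected
cell-wise onto the derived predictor fields.  Per variable, the hindcast
density is the mean over cross-validation folds of 10^f̂(x) (averaging on
the linear density scale), with 95% bands from the fold percentiles.  The
per-cell density is then the *minimum* across retained variables — Liebig's
law of the minimum — and the argmin variable is the limiting factor.  Cells
are occupied where density exceeds the viability threshold d_min
(0.2 persons/100 km², strict), and the continental population size is the
sum of density/100 × cell area over occupied ice-free cells.

A non-analogy screen keeps a variable at a time step only while its
paleoclimate values remain inside the ensemble's training domain: the
default "variable" policy compares the continental ice-free area-weighted
mean against the pooled training range (dropping a variable wholesale, the
way MWM is dropped in the archival analysis); the "cell" policy instead
masks out-of-range cells per variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .ethnography import EARTH_RADIUS_KM
from .predictors import VARIABLE_ORDER, derive_predictor_arrays, PredictorConfig, \
    DEFAULT_PREDICTOR_CONFIG
from .qgam import EnsembleModel

logger = logging.getLogger(__name__)

D_MIN_DEFAULT = 0.2  # persons / 100 km²; occupancy is strict (> d_min)
T_VARS = [f"t{m:02d}" for m in range(1, 13)]
P_VARS = [f"p{m:02d}" for m in range(1, 13)]


def _order_key(variable_id: str) -> int:
    return VARIABLE_ORDER.index(variable_id)


# ---------------------------------------------------------------------------
# predictors on cubes
# ---------------------------------------------------------------------------

def derive_predictor_cube(cube: xr.Dataset,
                          cfg: PredictorConfig = DEFAULT_PREDICTOR_CONFIG) -> xr.Dataset:
    """Apply the ten-predictor derivation cell-wise to a monthly cube."""
    missing = [v for v in T_VARS + P_VARS if v not in cube]
    if missing:
        raise ValueError(f"cube lacks monthly fields: {missing}")
    t = np.stack([cube[v].values for v in T_VARS])
    p = np.stack([cube[v].values for v in P_VARS])
    lat = np.broadcast_to(cube["lat"].values[None, :, None], t.shape[1:])
    arrays = derive_predictor_arrays(t, p, lat, cfg)
    return xr.Dataset({k: (("time", "lat", "lon"), v) for k, v in arrays.items()},
                      coords=cube.coords)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def cell_area_km2(lat_center, resolution_lat: float, resolution_lon: float | None = None):
    """Area of a lat/lon cell: R²·Δλ·(sin φ_top − sin φ_bottom)."""
    if resolution_lon is None:
        resolution_lon = resolution_lat
    lat = np.asarray(lat_center, float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    top = np.deg2rad(np.clip(lat + resolution_lat / 2.0, -90.0, 90.0))
    bot = np.deg2rad(np.clip(lat - resolution_lat / 2.0, -90.0, 90.0))
    dlon = np.deg2rad(resolution_lon)
    area = EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))
    return area if np.ndim(area) else float(area)


def grid_cell_areas(lat_centers: np.ndarray, n_lon: int,
                    resolution_lat: float, resolution_lon: float) -> np.ndarray:
    """(nlat, nlon) cell areas in km²."""
    col = cell_area_km2(np.asarray(lat_centers, float), resolution_lat, resolution_lon)
    return np.repeat(np.asarray(col)[:, None], n_lon, axis=1)


# ---------------------------------------------------------------------------
# screen, projection, Liebig engine
# ---------------------------------------------------------------------------

def analog_screen(ensembles: dict[str, EnsembleModel], predictor_cube: xr.Dataset,
                  ice_mask: xr.DataArray | None = None, policy: str = "variable",
                  areas: np.ndarray | None = None
                  ) -> tuple[dict[int, list[str]], dict[str, np.ndarray] | None]:
    """Which variables may be projected at each time step.

    Returns ``(retained, cell_masks)``: ``retained`` maps time index → list
    of retained variable ids; for the "cell" policy ``cell_masks`` maps
    variable id → boolean (time, lat, lon) validity array (True = in the
    training domain), otherwise None.
    """
    if policy not in ("variable", "cell"):
        raise ValueError("policy must be 'variable' or 'cell'")
    times = predictor_cube["time"].values
    nt = len(times)
    ice = (ice_mask.values if ice_mask is not None
           else np.zeros((nt,) + predictor_cube[list(ensembles)[0]].shape[1:], bool))
    if areas is None:
        areas = np.ones(predictor_cube[list(ensembles)[0]].shape[1:])

    retained: dict[int, list[str]] = {ti: [] for ti in range(nt)}
    cell_masks: dict[str, np.ndarray] = {}
    for vid in sorted(ensembles, key=_order_key):
        lo, hi = ensembles[vid].train_range
        vals = predictor_cube[vid].values
        inside = (vals >= lo) & (vals <= hi)
        cell_masks[vid] = inside
        for ti in range(nt):
            free = ~ice[ti]
            if policy == "variable":
                w = np.where(free, areas, 0.0)
                if w.sum() == 0:
                    continue
                mean = float(np.average(vals[ti], weights=w))
                if lo <= mean <= hi:
                    retained[ti].append(vid)
                else:
                    logger.info("analog screen: %s excluded at %.1f kyBP "
                                "(mean %.3g outside [%.3g, %.3g])",
                                vid, times[ti], mean, lo, hi)
            else:
                if inside[ti][free].any():
                    retained[ti].append(vid)
    for ti in range(nt):
        if not retained[ti]:
            raise RuntimeError(
                f"analog screen excluded every variable at {times[ti]} kyBP")
    return retained, (cell_masks if policy == "cell" else None)


@dataclass
class DensitySurface:
    """Per-variable hindcast surfaces at one time step."""

    mean: np.ndarray  # persons/100 km², linear scale
    lo: np.ndarray
    hi: np.ndarray
    folds: np.ndarray  # (n_folds, nlat, nlon) linear-scale densities


def predict_density_surface(ensemble: EnsembleModel, predictor_cube: xr.Dataset,
                            time_index: int, cell_mask: np.ndarray | None = None,
                            ci: tuple[float, float] = (2.5, 97.5)) -> DensitySurface:
    """Project one ensemble at one time step.

    Fold curves are evaluated with clamped extrapolation (the analog screen
    governs whether the variable is used at all); cells excluded by a
    cell-level mask become NaN.
    """
    x = predictor_cube[ensemble.variable_id].values[time_index]
    shape = x.shape
    preds = ensemble.predict_folds(x.ravel())  # log10 density
    dens = 10.0 ** preds
    mean = dens.mean(axis=0).reshape(shape)
    lo = np.percentile(dens, ci[0], axis=0).reshape(shape)
    hi = np.percentile(dens, ci[1], axis=0).reshape(shape)
    folds = dens.reshape((dens.shape[0],) + shape)
    if cell_mask is not None:
        bad = ~cell_mask
        mean = np.where(bad, np.nan, mean)
        lo = np.where(bad, np.nan, lo)
        hi = np.where(bad, np.nan, hi)
        folds = np.where(bad[None], np.nan, folds)
    return DensitySurface(mean=mean, lo=lo, hi=hi, folds=folds)


def liebig_minimum(per_variable_grids: dict[str, np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element-wise minimum and argmin variable over retained grids.

    Returns (density, factor_codes, tie_mask); codes index
    :data:`VARIABLE_ORDER`; cells where every variable is NaN are NaN with
    code −1.  Ties go to the earliest variable in the fixed order.
    """
    if not per_variable_grids:
        raise ValueError("need at least one variable grid")
    vids = sorted(per_variable_grids, key=_order_key)
    stack = np.stack([np.asarray(per_variable_grids[v], float) for v in vids])
    all_nan = np.all(np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        filled = np.where(np.isnan(stack), np.inf, stack)
        which = np.argmin(filled, axis=0)
        dens = np.take_along_axis(filled, which[None], axis=0)[0]
        n_at_min = np.sum(filled == dens[None], axis=0)
    tie = (n_at_min > 1) & ~all_nan
    codes = np.array([VARIABLE_ORDER.index(v) for v in vids], dtype=np.int16)[which]
    dens = np.where(all_nan, np.nan, dens)
    codes = np.where(all_nan, np.int16(-1), codes)
    return dens, codes, tie


def occupancy(density: np.ndarray, d_min: float = D_MIN_DEFAULT) -> np.ndarray:
    """Occupied ⇔ density strictly above d_min; NaN density is unoccupied."""
    with np.errstate(invalid="ignore"):
        return np.asarray(density, float) > d_min


def population_size(density: np.ndarray, occupied: np.ndarray,
                    ice_free: np.ndarray, areas_km2: np.ndarray) -> float:
    """Σ density/100 × area over occupied, ice-free cells (persons)."""
    sel = np.asarray(occupied, bool) & np.asarray(ice_free, bool)
    d = np.where(sel & np.isfinite(density), density, 0.0)
    return float(np.sum(d / 100.0 * areas_km2))


def modal_limiting_factor(fold_factor_grids: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell modal variable code across folds; ties → fixed order.

    ``fold_factor_grids`` is (n_folds, ...) of codes into VARIABLE_ORDER
    (−1 = missing).  Returns (codes, tie_mask).
    """
    grids = np.asarray(fold_factor_grids)
    if grids.shape[0] < 2:
        raise ValueError("modal factor needs at least 2 fold grids")
    n_codes = len(VARIABLE_ORDER)
    counts = np.zeros((n_codes,) + grids.shape[1:], dtype=np.int32)
    for c in range(n_codes):
        counts[c] = np.sum(grids == c, axis=0)
    total = counts.sum(axis=0)
    best = counts.max(axis=0)
    mode = counts.argmax(axis=0).astype(np.int16)  # argmax: first max → fixed order
    tie = (np.sum(counts == best[None], axis=0) > 1) & (total > 0)
    mode = np.where(total == 0, np.int16(-1), mode)
    return mode, tie


# ---------------------------------------------------------------------------
# full hindcast
# ---------------------------------------------------------------------------

@dataclass
class HindcastResult:
    """Density, limiting-factor, occupancy and population-size hindcast."""

    density: xr.DataArray  # (time, lat, lon) persons/100 km²
    density_lo: xr.DataArray
    density_hi: xr.DataArray
    limiting_factor: xr.DataArray  # int codes into VARIABLE_ORDER, −1 missing
    factor_tie: xr.DataArray
    occupancy: xr.DataArray  # bool
    ice_mask: xr.DataArray
    areas_km2: np.ndarray
    series: pd.DataFrame  # time_kyBP, pop_size, pop_lo, pop_hi, occupied_fraction
    excluded_variables: dict[float, list[str]]
    variable_ids: list[str]
    d_min: float


def run_hindcast(ensembles: dict[str, EnsembleModel], cube: xr.Dataset,
                 ice_mask: xr.DataArray, d_min: float = D_MIN_DEFAULT,
                 analogy_policy: str = "variable",
                 predictor_cube: xr.Dataset | None = None) -> HindcastResult:
    """Project ensembles over all time steps and assemble the hindcast.

    ``cube`` may be a monthly cube (predictors derived here) or pass a
    pre-derived ``predictor_cube``.  Central density is the Liebig minimum
    of fold-mean surfaces; bands apply the same minimum to the fold
    percentile surfaces; the limiting factor is the modal per-fold argmin.
    """
    if predictor_cube is None:
        predictor_cube = derive_predictor_cube(cube)
    times = predictor_cube["time"].values
    lat = predictor_cube["lat"].values
    lon = predictor_cube["lon"].values
    nt, nlat, nlon = len(times), len(lat), len(lon)
    if ice_mask.shape != (nt, nlat, nlon):
        raise ValueError("ice mask shape does not match the cube")

    res_lat = float(abs(lat[1] - lat[0])) if nlat > 1 else 1.0
    res_lon = float(abs(lon[1] - lon[0])) if nlon > 1 else 1.0
    areas = grid_cell_areas(lat, nlon, res_lat, res_lon)

    retained, cell_masks = analog_screen(ensembles, predictor_cube,
                                         ice_mask=ice_mask, policy=analogy_policy,
                                         areas=areas)
    all_vids = sorted(ensembles, key=_order_key)

    dens = np.full((nt, nlat, nlon), np.nan)
    dens_lo = np.full_like(dens, np.nan)
    dens_hi = np.full_like(dens, np.nan)
    factor = np.full((nt, nlat, nlon), -1, dtype=np.int16)
    tie = np.zeros((nt, nlat, nlon), bool)
    rows = []
    excluded: dict[float, list[str]] = {}

    for ti, t in enumerate(times):
        vids = retained[ti]
        excluded[float(t)] = [v for v in all_vids if v not in vids]
        surfaces = {v: predict_density_surface(
            ensembles[v], predictor_cube, ti,
            cell_mask=None if cell_masks is None else cell_masks[v][ti])
            for v in vids}

        dens[ti], _, _ = liebig_minimum({v: s.mean for v, s in surfaces.items()})
        dens_lo[ti], _, _ = liebig_minimum({v: s.lo for v, s in surfaces.items()})
        dens_hi[ti], _, _ = liebig_minimum({v: s.hi for v, s in surfaces.items()})

        # per-fold Liebig argmin → modal limiting factor
        n_folds = min(s.folds.shape[0] for s in surfaces.values())
        fold_codes = np.empty((n_folds, nlat, nlon), dtype=np.int16)
        for k in range(n_folds):
            _, fold_codes[k], _ = liebig_minimum(
                {v: s.folds[k] for v, s in surfaces.items()})
        factor[ti], tie[ti] = modal_limiting_factor(fold_codes)

        free = ~ice_mask.values[ti]
        occ = occupancy(dens[ti], d_min) & free
        pop = population_size(dens[ti], occ, free, areas)
        occ_lo = occupancy(dens_lo[ti], d_min) & free
        occ_hi = occupancy(dens_hi[ti], d_min) & free
        pop_lo = population_size(dens_lo[ti], occ_lo, free, areas)
        pop_hi = population_size(dens_hi[ti], occ_hi, free, areas)
        n_free = int(free.sum())
        rows.append({"time_kyBP": float(t), "pop_size": pop, "pop_lo": pop_lo,
                     "pop_hi": pop_hi,
                     "occupied_fraction": float(occ.sum()) / n_free if n_free else 0.0})

    coords = {"time": times, "lat": lat, "lon": lon}
    dims = ("time", "lat", "lon")
    occ_all = xr.DataArray(occupancy(dens, d_min) & ~ice_mask.values,
                           coords=coords, dims=dims, name="occupancy")
    lf = xr.DataArray(np.where(ice_mask.values, np.int16(-1), factor),
                      coords=coords, dims=dims, name="limiting_factor")
    lf.attrs["variable_ids"] = list(VARIABLE_ORDER)
    return HindcastResult(
        density=xr.DataArray(dens, coords=coords, dims=dims, name="density"),
        density_lo=xr.DataArray(dens_lo, coords=coords, dims=dims, name="density_lo"),
        density_hi=xr.DataArray(dens_hi, coords=coords, dims=dims, name="density_hi"),
        limiting_factor=lf,
        factor_tie=xr.DataArray(tie, coords=coords, dims=dims, name="factor_tie"),
        occupancy=occ_all, ice_mask=ice_mask, areas_km2=areas,
        series=pd.DataFrame(rows), excluded_variables=excluded,
        variable_ids=all_vids, d_min=d_min)
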