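"""Readers and writers for the pipeline's on-disk formats.

Formats: ethnographic table and radiocarbon dates as CSV, monthly climate
cubes / ice masks / hindcast surfaces as CF-style NetCDF with dims
(time, lat, lon) — written through xarray's scipy backend (NetCDF-3
classic) — ensemble models as self-describing JSON, and a JSON provenance
sidecar per run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .ethnography import EthnographicRecord
from .hindcast import HindcastResult
from .predictors import MonthlyClimate, derive_predictors
from .qgam import EnsembleModel, QuantileFit

logger = logging.getLogger(__name__)

T_COLS = [f"t{m:02d}" for m in range(1, 13)]
P_COLS = [f"p{m:02d}" for m in range(1, 13)]
ETHNO_COLUMNS = ["id", "lat", "lon", "density_per_100km2", "subsistence_class",
                 "years_at_location", "aquatic_protein_pct", "equestrian",
                 *T_COLS, *P_COLS]
_NETCDF_KW = dict(engine="scipy")  # NetCDF-3 classic


# ---------------------------------------------------------------------------
# ethnographic CSV
# ---------------------------------------------------------------------------

def write_ethnographic_csv(records: list[EthnographicRecord], path) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, "lat": r.lat, "lon": r.lon,
               "density_per_100km2": r.density,
               "subsistence_class": r.subsistence_class,
               "years_at_location": r.years_at_location,
               "aquatic_protein_pct": r.aquatic_protein_pct,
               "equestrian": r.equestrian}
        mc = r.monthly_climate
        if mc is None:
            raise ValueError(f"record {r.id} lacks monthly climate")
        row.update({c: mc.t_monthly[i] for i, c in enumerate(T_COLS)})
        row.update({c: mc.p_monthly[i] for i, c in enumerate(P_COLS)})
        rows.append(row)
    pd.DataFrame(rows, columns=ETHNO_COLUMNS).to_csv(path, index=False)


def read_ethnographic_csv(path, derive: bool = True) -> list[EthnographicRecord]:
    """Read and validate the ethnographic table; invalid rows are skipped.

    A missing required column is a hard error naming the column; a row that
    fails validation (e.g. density ≤ 0) is skipped and logged with its line
    number.
    """
    df = pd.read_csv(path)
    missing = [c for c in ETHNO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ethnographic CSV missing required column(s): {missing}")
    records: list[EthnographicRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            mc = MonthlyClimate(
                np.array([row[c] for c in T_COLS], float),
                np.array([row[c] for c in P_COLS], float),
                lat=float(row["lat"]))
            rec = EthnographicRecord(
                id=str(row["id"]), lat=float(row["lat"]), lon=float(row["lon"]),
                density=float(row["density_per_100km2"]),
                subsistence_class=str(row["subsistence_class"]),
                years_at_location=float(row["years_at_location"]),
                aquatic_protein_pct=float(row["aquatic_protein_pct"]),
                equestrian=_parse_bool(row["equestrian"]),
                monthly_climate=mc,
                predictors=derive_predictors(mc) if derive else None)
        except (ValueError, TypeError) as exc:
            logger.warning("skipping line %d of %s: %s", line_no, path, exc)
            continue
        records.append(rec)
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {v!r}")


# ---------------------------------------------------------------------------
# climate cubes
# ---------------------------------------------------------------------------

def write_climate_cube(cube: xr.Dataset, path) -> None:
    cube.to_netcdf(path, **_NETCDF_KW)


def read_climate_cube(path, monthly: bool = True) -> xr.Dataset:
    """Read a cube and validate axes: time strictly decreasing in kyBP,
    lat/lon monotone, monthly fields present when ``monthly``."""
    ds = xr.load_dataset(path, **_NETCDF_KW)
    for dim in ("time", "lat", "lon"):
        if dim not in ds.dims:
            raise ValueError(f"cube lacks dimension {dim!r}")
    t = ds["time"].values
    if len(t) > 1 and not np.all(np.diff(t) < 0):
        raise ValueError("time axis must be strictly decreasing (kyBP)")
    for dim in ("lat", "lon"):
        v = ds[dim].values
        if len(v) > 1 and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
            raise ValueError(f"{dim} axis must be monotone")
    if monthly:
        missing = [c for c in T_COLS + P_COLS if c not in ds]
        if missing:
            raise ValueError(f"cube lacks monthly fields: {missing}")
    return ds


def write_ice_mask(ice: xr.DataArray, path) -> None:
    ice.astype(np.int8).to_dataset(name="ice").to_netcdf(path, **_NETCDF_KW)


def read_ice_mask(path) -> xr.DataArray:
    ds = xr.load_dataset(path, **_NETCDF_KW)
    if "ice" not in ds:
        raise ValueError("ice mask file lacks variable 'ice'")
    return ds["ice"].astype(bool)


# ---------------------------------------------------------------------------
# radiocarbon CSV
# ---------------------------------------------------------------------------

def write_radiocarbon_csv(table: pd.DataFrame, path) -> None:
    table[["site_id", "age_BP"]].to_csv(path, index=False)


def read_radiocarbon_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("site_id", "age_BP"):
        if c not in df.columns:
            raise ValueError(f"radiocarbon CSV missing column {c!r}")
    return df


# ---------------------------------------------------------------------------
# ensemble model store (JSON)
# ---------------------------------------------------------------------------

def save_ensemble(model: EnsembleModel, path) -> None:
    payload = {
        "variable_id": model.variable_id,
        "tau": model.tau,
        "lam": model.lam,
        "metrics": model.metrics,
        "fold_train_indices": [f.tolist() for f in model.fold_train_indices],
        "fold_test_indices": [f.tolist() for f in model.fold_test_indices],
        "fits": [{
            "knots": f.knots.tolist(),
            "coefficients": f.coefficients.tolist(),
            "lam": f.lam,
            "train_range": list(f.train_range),
            "deviance_explained": f.deviance_explained,
            "n_train": f.n_train,
        } for f in model.fits],
    }
    Path(path).write_text(json.dumps(payload))


def load_ensemble(path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    fits = [QuantileFit(
        variable_id=payload["variable_id"], tau=payload["tau"],
        knots=np.array(f["knots"]), coefficients=np.array(f["coefficients"]),
        lam=f["lam"], train_range=tuple(f["train_range"]),
        deviance_explained=f["deviance_explained"], n_train=f["n_train"])
        for f in payload["fits"]]
    return EnsembleModel(
        variable_id=payload["variable_id"], tau=payload["tau"], fits=fits,
        fold_train_indices=[np.array(i, int) for i in payload["fold_train_indices"]],
        fold_test_indices=[np.array(i, int) for i in payload["fold_test_indices"]],
        metrics=payload["metrics"], lam=payload["lam"])


# ---------------------------------------------------------------------------
# hindcast outputs
# ---------------------------------------------------------------------------

def write_hindcast(result: HindcastResult, out_dir) -> dict[str, Path]:
    """Write NetCDF surfaces, the CSV time series and the exclusion log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lf = result.limiting_factor.astype(np.int16)
    lf.attrs = {}  # the NetCDF-3 writer cannot hold list attributes
    ds = xr.Dataset({
        "density": result.density,
        "density_lo": result.density_lo,
        "density_hi": result.density_hi,
        "limiting_factor": lf,
        "occupancy": result.occupancy.astype(np.int8),
        "ice": result.ice_mask.astype(np.int8),
    })
    ds.attrs["variable_ids"] = " ".join(result.limiting_factor.attrs["variable_ids"])
    ds.attrs["d_min"] = result.d_min
    paths = {
        "surfaces": out / "hindcast_surfaces.nc",
        "series": out / "population_series.csv",
        "excluded": out / "excluded_variables.json",
    }
    ds.to_netcdf(paths["surfaces"], **_NETCDF_KW)
    result.series.to_csv(paths["series"], index=False)
    paths["excluded"].write_text(json.dumps(
        {str(k): v for k, v in result.excluded_variables.items()}, indent=2))
    return paths


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config_dict: dict, seeds: dict | None = None) -> None:
    from . import __version__
    payload = {"config_hash": config_hash(config_dict), "config": config_dict,
               "seeds": seeds or {}, "paleopop_version": __version__,
               "numpy_version": np.__version__}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
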