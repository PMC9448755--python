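"""Continental summaries of the hindcast and radiocarbon-proxy validation.

Covers the headline summary quantities of the analysis: the area share of
the ice-free continent attributed to each limiting factor through time,
mean inhabited density / occupied fraction / population size at named
climate-event snapshots (GS2, GI1, GS1, Holocene onset, Early Holocene),
continental predictor means, and the Pearson correlation between the
hindcast population series and a binned radiocarbon date-count proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import pearsonr

from .hindcast import HindcastResult
from .predictors import VARIABLE_ORDER


@dataclass(frozen=True)
class PeriodConfig:
    """Named climate-event snapshots (kyBP), resolvable to cube steps."""

    snapshots: dict[str, float] = field(default_factory=lambda: {
        "GS2": 21.0,      # Last Glacial Maximum interval
        "GI1": 14.7,      # interstadial warm peak
        "GS1": 11.7,      # stadial cold point (onset ~12.8)
        "HolInit": 11.7,  # Holocene onset
        "EHol": 8.0,      # Early Holocene
    })


@dataclass
class ProxySeries:
    """Radiocarbon date counts per millennium bin."""

    bin_centers_kyBP: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")


def limiting_factor_proportions(result: HindcastResult) -> pd.DataFrame:
    """Area-weighted share of ice-free area per limiting factor and step.

    Fractions over retained variables sum to 1 minus the reported missing
    remainder (cells without any valid prediction).
    """
    rows = []
    times = result.density["time"].values
    codes = result.limiting_factor.values
    ice = result.ice_mask.values
    for ti, t in enumerate(times):
        free = ~ice[ti]
        total = result.areas_km2[free].sum()
        if total == 0:
            continue
        for vi, vid in enumerate(VARIABLE_ORDER):
            sel = free & (codes[ti] == vi)
            frac = result.areas_km2[sel].sum() / total
            if vid in result.variable_ids:
                rows.append({"time_kyBP": float(t), "variable": vid,
                             "fraction": float(frac)})
        missing = free & (codes[ti] == -1)
        rows.append({"time_kyBP": float(t), "variable": "missing",
                     "fraction": float(result.areas_km2[missing].sum() / total)})
    return pd.DataFrame(rows)


def _nearest_time_index(times: np.ndarray, target: float) -> int:
    idx = int(np.argmin(np.abs(times - target)))
    if abs(times[idx] - target) > 0.51:
        raise ValueError(f"snapshot {target} kyBP outside the cube time span")
    return idx


def period_summary(result: HindcastResult,
                   periods: PeriodConfig | None = None) -> pd.DataFrame:
    """Mean inhabited density, occupied fraction and population per snapshot.

    Mean density is area-weighted over *occupied* cells only (the mean in
    the inhabited area), so empty cells never dilute it.
    """
    periods = periods or PeriodConfig()
    times = result.density["time"].values
    rows = []
    for name, t in periods.snapshots.items():
        ti = _nearest_time_index(times, t)
        occ = result.occupancy.values[ti]
        dens = result.density.values[ti]
        w = np.where(occ, result.areas_km2, 0.0)
        mean_dens = float(np.average(np.nan_to_num(dens), weights=w)) if w.sum() else float("nan")
        srow = result.series.iloc[ti]
        rows.append({"period": name, "time_kyBP": float(times[ti]),
                     "mean_inhabited_density": mean_dens,
                     "occupied_fraction": float(srow["occupied_fraction"]),
                     "pop_size": float(srow["pop_size"]),
                     "pop_lo": float(srow["pop_lo"]),
                     "pop_hi": float(srow["pop_hi"])})
    return pd.DataFrame(rows)


def continental_predictor_means(predictor_cube: xr.Dataset,
                                ice_mask: xr.DataArray,
                                areas_km2: np.ndarray) -> pd.DataFrame:
    """Area-weighted ice-free continental mean of each predictor per step."""
    times = predictor_cube["time"].values
    rows = []
    for ti, t in enumerate(times):
        free = ~ice_mask.values[ti]
        w = np.where(free, areas_km2, 0.0)
        for vid in predictor_cube.data_vars:
            vals = predictor_cube[vid].values[ti]
            mean = float(np.average(vals, weights=w)) if w.sum() else float("nan")
            rows.append({"time_kyBP": float(t), "variable": str(vid), "mean": mean})
    return pd.DataFrame(rows)


def bin_radiocarbon(ages_bp) -> ProxySeries:
    """Counts of dates per nearest-1000-year bin (half-up at the midpoint)."""
    ages = np.asarray(ages_bp, float)
    if ages.size and np.any(ages <= 0):
        raise ValueError("ages must be positive (years BP)")
    bins = np.floor(ages / 1000.0 + 0.5) * 1000.0
    centers, counts = np.unique(bins, return_counts=True)
    return ProxySeries(bin_centers_kyBP=centers / 1000.0,
                       counts=counts.astype(int))


def proxy_correlation(pop_series: pd.Series, proxy: ProxySeries,
                      window_kyBP: tuple[float, float] = (21.0, 10.0)
                      ) -> tuple[float, float]:
    """Pearson correlation of the hindcast population vs the proxy counts.

    ``pop_series`` is indexed by time (kyBP); it is aggregated to the proxy
    bins by the mean within each millennium before correlating over the
    overlapping window (defaults to the 21–10 kyBP validation window).
    Returns (rho, two-sided p).
    """
    hi, lo = max(window_kyBP), min(window_kyBP)
    times = np.asarray(pop_series.index, float)
    vals = np.asarray(pop_series.values, float)
    bins = np.floor(times + 0.5)
    pop_binned = {}
    for b in np.unique(bins):
        if lo <= b <= hi:
            pop_binned[b] = vals[bins == b].mean()
    xs, ys = [], []
    for c, n in zip(proxy.bin_centers_kyBP, proxy.counts):
        if c in pop_binned and lo <= c <= hi:
            xs.append(pop_binned[c])
            ys.append(float(n))
    if len(xs) < 3:
        raise ValueError("fewer than 3 overlapping bins for correlation")
    rho, p = pearsonr(xs, ys)
    return float(rho), float(p)
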