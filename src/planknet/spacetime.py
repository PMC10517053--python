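"""Gridded prediction of community types and long-term area trends.

Applies a trained classifier to monthly feature grids, converts the
per-cell multi-label predictions into per-region area series, and tests
those series for monotone trends with the seasonal Mann-Kendall test and
the seasonal Theil-Sen slope estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .classify import SATELLITE_FEATURES, TrainedClassifier
from .preprocess import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)


def downsample_grid(field: xr.Dataset, factor: int) -> xr.Dataset:
    """Keep the cell at local index (floor(factor/2), floor(factor/2)) of
    each factor x factor block; partial edge blocks are dropped. Pure
    selection — values are untouched."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return field
    n_lat = field.sizes["lat"] // factor
    n_lon = field.sizes["lon"] // factor
    if n_lat == 0 or n_lon == 0:
        raise ValueError("grid smaller than the downsampling factor")
    offset = factor // 2
    lat_idx = offset + factor * np.arange(n_lat)
    lon_idx = offset + factor * np.arange(n_lon)
    return field.isel(lat=lat_idx, lon=lon_idx)


@dataclass
class GridPrediction:
    """Per (time, cell) predicted type set, argmax type and max probability.

    ``type_mask`` is a bitmask over ``classes`` (bit j set = classes[j]
    predicted); ``argmax`` holds the highest-probability class id, or 0 where
    no prediction was made; ``none_flag`` marks cells with no type above
    threshold OR missing inputs (``missing`` distinguishes the latter)."""

    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    classes: np.ndarray
    type_mask: np.ndarray  # (time, lat, lon) int
    argmax: np.ndarray  # (time, lat, lon) int, 0 = none
    max_prob: np.ndarray  # (time, lat, lon) float, nan where missing
    none_flag: np.ndarray  # (time, lat, lon) bool
    missing: np.ndarray  # (time, lat, lon) bool

    def predicted_set(self, t: int, i: int, j: int) -> set:
        mask = int(self.type_mask[t, i, j])
        return {int(c) for b, c in enumerate(self.classes) if mask >> b & 1}

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "type_mask": (("time", "lat", "lon"), self.type_mask),
                "argmax": (("time", "lat", "lon"), self.argmax),
                "max_prob": (("time", "lat", "lon"), self.max_prob),
                "none_flag": (("time", "lat", "lon"), self.none_flag),
                "missing": (("time", "lat", "lon"), self.missing),
            },
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            attrs={"classes": [int(c) for c in self.classes]},
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell records for evaluated (non-missing) cells."""
        t_idx, i_idx, j_idx = np.nonzero(~self.missing)
        return pd.DataFrame(
            {
                "time": self.time[t_idx],
                "lat": self.lat[i_idx],
                "lon": self.lon[j_idx],
                "argmax": self.argmax[t_idx, i_idx, j_idx],
                "max_prob": self.max_prob[t_idx, i_idx, j_idx],
                "none_flag": self.none_flag[t_idx, i_idx, j_idx],
                "type_mask": self.type_mask[t_idx, i_idx, j_idx],
            }
        )


def predict_map(
    model: TrainedClassifier,
    field: xr.Dataset,
    feature_names: list[str] | None = None,
) -> GridPrediction:
    """Predict the community-type set per grid cell and month.

    A class is in the predicted set when its probability is at least the
    model's probability threshold; the argmax class is recorded alongside.
    Cells with any missing parameter are none-flagged and marked missing.
    """
    names = feature_names or model.feature_names or SATELLITE_FEATURES
    absent = [f for f in names if f not in field.data_vars]
    if absent:
        raise ValueError(f"grid is missing feature variables: {absent}")
    stack = np.stack([field[f].values for f in names], axis=-1)  # (t, la, lo, F)
    t, la, lo, _ = stack.shape
    flat = stack.reshape(-1, stack.shape[-1])
    complete = ~np.isnan(flat).any(axis=1)

    classes = np.asarray(model.classes)
    prob = np.full((flat.shape[0], len(classes)), np.nan)
    if complete.any():
        prob[complete] = model.predict_proba(flat[complete])

    threshold = model.probability_threshold
    passed = np.zeros_like(prob, dtype=bool)
    passed[complete] = prob[complete] >= threshold
    bits = (1 << np.arange(len(classes)))
    type_mask = np.where(complete, passed @ bits, 0).astype(np.int64)
    arg_idx = np.zeros(flat.shape[0], dtype=np.int64)
    arg_idx[complete] = np.argmax(prob[complete], axis=1)
    argmax = np.where(complete & (type_mask > 0), classes[arg_idx], 0)
    max_prob = np.where(complete, np.nanmax(np.where(np.isnan(prob), -np.inf, prob), axis=1), np.nan)
    none_flag = ~complete | (type_mask == 0)

    shape3 = (t, la, lo)
    return GridPrediction(
        time=np.asarray(field["time"].values),
        lat=np.asarray(field["lat"].values, dtype=float),
        lon=np.asarray(field["lon"].values, dtype=float),
        classes=classes,
        type_mask=type_mask.reshape(shape3),
        argmax=argmax.reshape(shape3),
        max_prob=max_prob.reshape(shape3),
        none_flag=none_flag.reshape(shape3),
        missing=(~complete).reshape(shape3),
    )


def cell_area_km2(lat_deg: np.ndarray, dlat_deg: float, dlon_deg: float) -> np.ndarray:
    """Area of a dlat x dlon cell centered at the given latitude:
    (pi R / 180)^2 * dlat * dlon * cos(latitude)."""
    unit = (np.pi * EARTH_RADIUS_KM / 180.0) ** 2
    return unit * dlat_deg * dlon_deg * np.cos(np.radians(np.asarray(lat_deg, dtype=float)))


def _grid_steps(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 1.0
    return float(abs(np.diff(values).mean()))


def area_series(
    pred: GridPrediction,
    region_mask: np.ndarray | None = None,
    mode: str = "multilabel",
) -> pd.DataFrame:
    """Monthly area per (region, type) in km^2.

    ``region_mask`` maps each (lat, lon) cell to a region label; cells not
    covered get region "unmasked". In ``multilabel`` mode every type in a
    cell's predicted set receives the full cell area; in ``argmax`` mode only
    the argmax type does. Rows with type 0 report the none-flagged area.
    """
    if mode not in ("multilabel", "argmax"):
        raise ValueError("mode must be 'multilabel' or 'argmax'")
    n_lat, n_lon = len(pred.lat), len(pred.lon)
    if region_mask is None:
        region = np.full((n_lat, n_lon), "all", dtype=object)
    else:
        region = np.asarray(region_mask, dtype=object)
        if region.shape != (n_lat, n_lon):
            raise ValueError("region mask shape does not match the grid")
        unmask = pd.isna(pd.DataFrame(region)).to_numpy()
        if unmask.any():
            logger.warning("area_series: %d cells unmasked", int(unmask.sum()))
            region = np.where(unmask, "unmasked", region)

    dlat = _grid_steps(pred.lat)
    dlon = _grid_steps(pred.lon)
    areas = np.broadcast_to(
        cell_area_km2(pred.lat, dlat, dlon)[:, None], (n_lat, n_lon)
    )

    records = []
    regions = np.unique(region)
    for t, stamp in enumerate(pred.time):
        for reg in regions:
            in_reg = region == reg
            none_area = float(areas[in_reg & pred.none_flag[t]].sum())
            records.append(
                {"time": stamp, "region": reg, "type": 0, "area_km2": none_area}
            )
            for b, cls in enumerate(pred.classes):
                if mode == "multilabel":
                    has = (pred.type_mask[t] >> b & 1).astype(bool)
                else:
                    has = pred.argmax[t] == cls
                records.append(
                    {
                        "time": stamp,
                        "region": reg,
                        "type": int(cls),
                        "area_km2": float(areas[in_reg & has].sum()),
                    }
                )
    return pd.DataFrame(records)


def _kendall_s_var(x: np.ndarray) -> tuple[float, float]:
    """Kendall S statistic and tie-corrected variance for one season."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        return 0.0, 0.0
    sign = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(sign, 1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)))
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var


def seasonal_mann_kendall(series: np.ndarray, period: int = 12) -> tuple[float, str]:
    """Seasonal Mann-Kendall test: Kendall S per season over that season's
    yearly values, summed over seasons with additive variances; two-sided p
    from the normal approximation with continuity correction.

    Returns (p_value, direction) with direction in {"increasing",
    "decreasing", "none"}. Missing values (NaN) are ignored per season.
    """
    x = np.asarray(series, dtype=float)
    s_total, var_total = 0.0, 0.0
    for s in range(period):
        s_k, var_k = _kendall_s_var(x[s::period])
        s_total += s_k
        var_total += var_k
    if var_total == 0:
        return 1.0, "none"
    if s_total > 0:
        z = (s_total - 1) / np.sqrt(var_total)
    elif s_total < 0:
        z = (s_total + 1) / np.sqrt(var_total)
    else:
        z = 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    direction = "increasing" if s_total > 0 else "decreasing" if s_total < 0 else "none"
    return p, direction


def seasonal_sen_slope(series: np.ndarray, period: int = 12) -> float:
    """Seasonal Theil-Sen slope: the median of all within-season pairwise
    slopes (value difference over year difference), in units per year."""
    x = np.asarray(series, dtype=float)
    slopes = []
    usable_seasons = 0
    for s in range(period):
        xs = x[s::period]
        years = np.arange(len(xs), dtype=float)
        ok = ~np.isnan(xs)
        xs, years = xs[ok], years[ok]
        if len(xs) >= 2:
            usable_seasons += 1
            diff_x = xs[None, :] - xs[:, None]
            diff_t = years[None, :] - years[:, None]
            iu = np.triu_indices(len(xs), 1)
            slopes.append(diff_x[iu] / diff_t[iu])
    if usable_seasons == 0:
        raise ValueError("no season has at least 2 values")
    return float(np.median(np.concatenate(slopes)))


@dataclass
class TrendResult:
    region: str
    type_id: int
    p_value: float
    direction: str
    sen_slope_km2_per_year: float


def area_trends(area_table: pd.DataFrame, period: int = 12, alpha: float = 0.05) -> pd.DataFrame:
    """Seasonal MK p-value and Sen slope of the area series of every
    (region, type), from the output of :func:`area_series`."""
    rows = []
    for (reg, typ), group in area_table.groupby(["region", "type"]):
        series = group.sort_values("time")["area_km2"].to_numpy()
        if len(series) < 2 * period:
            continue
        p, direction = seasonal_mann_kendall(series, period)
        slope = seasonal_sen_slope(series, period)
        rows.append(
            {
                "region": reg,
                "type": typ,
                "p_value": p,
                "direction": direction,
                "significant": p < alpha,
                "sen_slope_km2_per_year": slope,
            }
        )
    return pd.DataFrame(rows)
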