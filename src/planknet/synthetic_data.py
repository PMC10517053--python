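"""Synthetic worlds with the statistical structure the pipeline assumes.

A latent environmental gradient (a temperature surrogate, monotone in
latitude) drives which planted OTU module is dominant at each sample, the
satellite features are smooth functions of the same gradient plus noise, and
sample locations are spatially clustered on the sphere. Ground truth (OTU
module membership, true community type, gradient value) is returned for
parameter-recovery tests.

Read counts follow a Dirichlet-multinomial: member OTUs of the locally
dominant module get a concentration boost, giving positive co-variation
across samples and the overdispersion typical of metabarcoding counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .preprocess import EARTH_RADIUS_KM, OtuTable

__all__ = [
    "WorldConfig",
    "GroundTruth",
    "generate_world",
    "generate_grid_series",
    "FEATURE_DEFS",
]


def _shape_bump(center: float, width: float):
    return lambda g: np.exp(-((g - center) ** 2) / (2 * width**2))


#: feature name -> (low, high, shape); value = low + (high - low) * shape(g),
#: with shape returning O(1) values. Noise is added on the shape scale.
FEATURE_DEFS: dict[str, tuple[float, float, object]] = {
    "rrs_412": (0.001, 0.012, lambda g: 1 - 0.8 * g),
    "rrs_443": (0.001, 0.010, lambda g: 1 - 0.6 * g**2),
    "rrs_469": (0.001, 0.009, lambda g: 0.9 - 0.5 * g),
    "rrs_488": (0.001, 0.008, lambda g: 0.5 + 0.4 * np.cos(np.pi * g)),
    "rrs_531": (0.001, 0.006, lambda g: 0.5 + 0.3 * np.sin(np.pi * g)),
    "rrs_547": (0.001, 0.006, _shape_bump(0.5, 0.25)),
    "rrs_555": (0.001, 0.005, _shape_bump(0.6, 0.3)),
    "rrs_645": (0.0001, 0.002, lambda g: 0.2 + 0.6 * g),
    "rrs_667": (0.0001, 0.002, lambda g: 0.1 + 0.7 * g * np.sqrt(np.abs(g))),
    "rrs_678": (0.0001, 0.002, lambda g: 0.15 + 0.6 * g**2),
    "chl_a": (0.02, 3.0, lambda g: np.exp(-3.0 * g)),
    "kd_490": (0.02, 0.25, lambda g: np.exp(-2.5 * g)),
    "poc": (20.0, 400.0, lambda g: np.exp(-2.0 * g)),
    "pic": (0.0001, 0.003, _shape_bump(0.35, 0.2)),
    "par": (15.0, 55.0, lambda g: g),
    "nflh": (0.01, 0.35, _shape_bump(0.25, 0.2)),
    # linear in the gradient: the SST surrogate used for trend injection
    "sst": (-2.0, 30.0, lambda g: g),
}

SST_PER_GRADIENT = FEATURE_DEFS["sst"][1] - FEATURE_DEFS["sst"][0]  # degC per unit g


@dataclass
class WorldConfig:
    """Parameters of a synthetic world; all randomness derives from seed."""

    n_samples: int = 120
    n_otus_per_module: int = 8
    n_modules: int = 4
    n_noise_otus: int = 10
    read_depth: int = 2000
    gradient_strength: float = 3.0
    feature_noise_sd: float = 0.02
    spatial_cluster_km: float = 300.0
    seed: int = 0
    samples_per_cluster: int = 5
    shallow_frac: float = 0.0
    base_concentration: float = 5.0
    start_year: int = 2009
    n_years: int = 9

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_otus_per_module", "n_modules", "n_noise_otus"):
            if getattr(self, name) < (0 if name == "n_noise_otus" else 1):
                raise ValueError(f"{name} must be positive")
        if self.read_depth < 100:
            raise ValueError("read_depth must be >= 100")
        if not (0 <= self.shallow_frac < 1):
            raise ValueError("shallow_frac must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure: OTU module membership (0 = noise), true community
    type per sample, and the latent gradient value per sample."""

    otu_module: dict[str, int]
    sample_type: dict[str, int]
    latent_gradient: dict[str, float]


def _gradient_from_latitude(lat: np.ndarray) -> np.ndarray:
    """Temperature-like surrogate, decreasing monotonically with latitude."""
    return np.clip((70.0 - np.asarray(lat, dtype=float)) / 140.0, 0.0, 1.0)


def _module_activations(g: np.ndarray, n_modules: int) -> np.ndarray:
    """(n_samples, K) Gaussian activation of each module along the gradient."""
    centers = (np.arange(1, n_modules + 1) - 0.5) / n_modules
    width = 0.5 / n_modules
    return np.exp(-((g[:, None] - centers[None, :]) ** 2) / (2 * width**2))


def _great_circle_offset(lat, lon, bearing, dist_km):
    """Destination point given start, initial bearing and distance."""
    delta = dist_km / EARTH_RADIUS_KM
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(bearing)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(bearing) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lat2 = np.degrees(phi2)
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    lon2 = np.where(lon2 == -180.0, 180.0, lon2)
    return lat2, lon2


def sample_locations(
    n_samples: int, cluster_km: float, samples_per_cluster: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster centers at uniform latitudes in [-70, 70]; members jittered by
    great-circle offsets of at most the cluster radius. Returns latitudes,
    longitudes and the cluster index of every sample."""
    n_clusters = max(1, math.ceil(n_samples / samples_per_cluster))
    center_lat = rng.uniform(-70.0, 70.0, n_clusters)
    center_lon = rng.uniform(-180.0, 180.0, n_clusters)
    cluster = np.repeat(np.arange(n_clusters), samples_per_cluster)[:n_samples]
    bearing = rng.uniform(0, 2 * np.pi, n_samples)
    dist = cluster_km * np.sqrt(rng.uniform(0, 1, n_samples))
    lat, lon = _great_circle_offset(
        center_lat[cluster], center_lon[cluster], bearing, dist
    )
    return lat, lon, cluster


def feature_table(g: np.ndarray, noise_sd: float, rng: np.random.Generator) -> pd.DataFrame:
    """The 17 satellite parameters as smooth functions of the gradient plus
    independent Gaussian noise of sd ``noise_sd`` on the shape scale."""
    g = np.asarray(g, dtype=float)
    cols = {}
    for name, (lo, hi, shape) in FEATURE_DEFS.items():
        vals = shape(g) + noise_sd * rng.standard_normal(g.shape)
        cols[name] = lo + (hi - lo) * vals
    return pd.DataFrame(cols)


def generate_world(
    config: WorldConfig,
) -> tuple[OtuTable, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (OtuTable, SampleMeta, SatelliteFeatures, GroundTruth).

    One child random stream per generated object, all derived from the
    single seed, so regenerating any one piece is stable.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_space, rng_counts, rng_feat, rng_meta, rng_floor = (
        np.random.default_rng(s) for s in streams
    )
    K = config.n_modules
    n = config.n_samples

    lat, lon, _ = sample_locations(
        n, config.spatial_cluster_km, config.samples_per_cluster, rng_space
    )
    g = _gradient_from_latitude(lat)
    act = _module_activations(g, K)
    sample_type = act.argmax(axis=1) + 1

    sample_ids = [f"s{i:04d}" for i in range(n)]
    otu_ids = [
        f"mod{m}_otu{j}" for m in range(1, K + 1) for j in range(config.n_otus_per_module)
    ] + [f"noise_otu{j}" for j in range(config.n_noise_otus)]
    otu_module = {o: (int(o[3: o.index("_")]) if o.startswith("mod") else 0) for o in otu_ids}
    module_of = np.array([otu_module[o] for o in otu_ids])

    # concentration boost for members of locally activated modules
    conc = np.full((n, len(otu_ids)), config.base_concentration, dtype=float)
    for m in range(1, K + 1):
        boost = np.exp(config.gradient_strength * act[:, m - 1])
        conc[:, module_of == m] *= boost[:, None]

    counts = np.empty((n, len(otu_ids)), dtype=np.int64)
    for i in range(n):
        p = rng_counts.dirichlet(conc[i])
        counts[i] = rng_counts.multinomial(config.read_depth, p)
    table = OtuTable(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts)

    features = feature_table(g, config.feature_noise_sd, rng_feat)
    features.insert(0, "sample_id", sample_ids)

    years = rng_meta.integers(config.start_year, config.start_year + config.n_years, n)
    months = rng_meta.integers(1, 13, n)
    seafloor = rng_floor.uniform(1000.0, 5000.0, n)
    n_shallow = int(round(config.shallow_frac * n))
    if n_shallow:
        shallow_idx = rng_floor.choice(n, size=n_shallow, replace=False)
        seafloor[shallow_idx] = rng_floor.uniform(10.0, 199.0, n_shallow)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "latitude": lat,
            "longitude": lon,
            "date": [f"{y}-{m:02d}" for y, m in zip(years, months)],
            "sampling_depth_m": 5.0,
            "seafloor_depth_m": seafloor,
            "size_fraction": "0.8-5um",
        }
    )

    truth = GroundTruth(
        otu_module=otu_module,
        sample_type={s: int(t) for s, t in zip(sample_ids, sample_type)},
        latent_gradient={s: float(v) for s, v in zip(sample_ids, g)},
    )
    return table, meta, features, truth


def generate_grid_series(
    n_years: int,
    grid_shape: tuple[int, int],
    trend_per_year: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    seasonal_amplitude: float = 1.5,
    noise_sd: float = 0.01,
    start_year: int = 2003,
) -> xr.Dataset:
    """Monthly feature grids driven by a latent gradient field that carries a
    seasonal cycle plus a linear trend of known slope.

    ``trend_per_year`` and ``seasonal_amplitude`` are expressed in units of
    the SST surrogate (degC), converted internally to gradient drift so every
    feature shifts consistently. ``missing_rate`` masks that fraction of
    (time, cell) entries across all parameters.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)

    lat = np.linspace(65.0, -65.0, rows)
    lon = np.linspace(-179.0, 179.0, cols)
    n_months = 12 * n_years
    time = pd.period_range(start=f"{start_year}-01", periods=n_months, freq="M")

    g_base = _gradient_from_latitude(lat)[:, None] * np.ones((1, cols))
    months = np.arange(n_months)
    season = (seasonal_amplitude / SST_PER_GRADIENT) * np.sin(2 * np.pi * (months % 12) / 12.0)
    trend = (trend_per_year / SST_PER_GRADIENT) * (months / 12.0)
    g = g_base[None, :, :] + (season + trend)[:, None, None]

    mask = rng.uniform(size=(n_months, rows, cols)) < missing_rate
    data_vars = {}
    for name, (lo, hi, shape) in FEATURE_DEFS.items():
        vals = shape(g) + noise_sd * rng.standard_normal(g.shape)
        vals = lo + (hi - lo) * vals
        vals = np.where(mask, np.nan, vals)
        data_vars[name] = (("time", "lat", "lon"), vals)
    data_vars["gradient"] = (("time", "lat", "lon"), np.where(mask, np.nan, g))
    ds = xr.Dataset(
        data_vars,
        coords={"time": time.astype(str), "lat": lat, "lon": lon},
        attrs={"seed": seed, "trend_per_year": trend_per_year},
    )
    return ds
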