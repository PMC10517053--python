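"""Sample/OTU preprocessing: rarefaction, spatio-temporal binning, open-ocean
filtering, spatial thinning, occurrence filtering and the centered log-ratio
transform.

Conventions
-----------
* An :class:`OtuTable` stores counts as samples x OTUs. The on-disk TSV
  dialect is transposed (OTUs as rows, samples as columns), matching the
  common occurrence-table layout.
* Sample metadata travels as a :class:`pandas.DataFrame` with columns
  ``sample_id, latitude, longitude, date, sampling_depth_m, seafloor_depth_m,
  size_fraction``; ``date`` is a ``YYYY-MM`` string.
* All great-circle distances use the haversine formula with an Earth radius
  of 6371 km, shared by thinning and buffered cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

META_COLUMNS = [
    "sample_id",
    "latitude",
    "longitude",
    "date",
    "sampling_depth_m",
    "seafloor_depth_m",
    "size_fraction",
]


@dataclass
class OtuTable:
    """Read-count table, samples as rows and OTUs as columns.

    Counts are non-negative; they are integers before binning and may be
    non-integer averages afterwards.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # (n_samples, n_otus)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("otu ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_frame(self) -> pd.DataFrame:
        """OTUs as rows, samples as columns (the TSV dialect)."""
        return pd.DataFrame(
            self.counts.T, index=self.otu_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OtuTable":
        return cls(
            sample_ids=[str(c) for c in frame.columns],
            otu_ids=[str(i) for i in frame.index],
            counts=frame.to_numpy().T,
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "otu_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "OtuTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class ClrMatrix:
    """Centered log-ratio values; every row sums to zero."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray  # (n_samples, n_otus), rows sum to 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.otu_ids
        )


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon <= -180) | (lon > 180)):
        raise ValueError("longitude out of (-180, 180]")
    return meta


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (and logged). Uses a
    multivariate hypergeometric draw per sample, which is equivalent to
    drawing ``depth`` reads without replacement.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    counts = np.asarray(table.counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefy expects integer read counts")
    counts = np.round(counts).astype(np.int64)
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropped %d samples below depth %d: %s",
            len(dropped), depth, dropped,
        )
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(counts[keep]):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    if out.shape[0] == 0:
        logger.warning("rarefy: no samples retained at depth %d", depth)
    return OtuTable(
        sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
        otu_ids=list(table.otu_ids),
        counts=out,
    )


def _month_key(date: str) -> str:
    # normalize "YYYY-MM" / "YYYY-MM-DD" to "YYYY-MM"
    period = pd.Period(str(date), freq="M")
    return str(period)


def bin_samples(
    table: OtuTable,
    meta: pd.DataFrame,
    cell_arcmin: float = 5.0,
    by_month: bool = True,
) -> tuple[OtuTable, pd.DataFrame]:
    """Average samples sharing a square grid cell (and calendar month) into
    one pseudo-sample.

    Bin metadata carries the cell-center coordinates and the month; the other
    metadata columns take the first member's value.
    """
    validate_meta(meta)
    if list(meta["sample_id"]) != list(table.sample_ids):
        raise ValueError("metadata sample order does not match table")
    cell_deg = cell_arcmin / 60.0
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    row_idx = np.floor((lat + 90.0) / cell_deg).astype(int)
    col_idx = np.floor((lon + 180.0) / cell_deg).astype(int)
    months = (
        [_month_key(d) for d in meta["date"]] if by_month else ["*"] * len(meta)
    )
    keys = list(zip(row_idx, col_idx, months))
    order: dict[tuple, int] = {}
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        if key not in groups:
            order[key] = len(order)
            groups[key] = []
        groups[key].append(i)

    new_counts = np.empty((len(groups), table.n_otus), dtype=float)
    new_rows = []
    new_ids = []
    for key, members in groups.items():
        g = order[key]
        new_counts[g] = table.counts[members].mean(axis=0)
        r, c, month = key
        center_lat = (r + 0.5) * cell_deg - 90.0
        center_lon = (c + 0.5) * cell_deg - 180.0
        first = meta.iloc[members[0]]
        bin_id = f"bin_{r}_{c}_{month}"
        new_ids.append(bin_id)
        new_rows.append(
            {
                "sample_id": bin_id,
                "latitude": center_lat,
                "longitude": center_lon,
                "date": month if by_month else _month_key(first["date"]),
                "sampling_depth_m": first["sampling_depth_m"],
                "seafloor_depth_m": first["seafloor_depth_m"],
                "size_fraction": first["size_fraction"],
                "n_members": len(members),
                "members": ";".join(meta["sample_id"].iloc[m] for m in members),
            }
        )
    binned_meta = pd.DataFrame(new_rows)
    logger.info("bin_samples: %d samples -> %d bins", table.n_samples, len(groups))
    return (
        OtuTable(sample_ids=new_ids, otu_ids=list(table.otu_ids), counts=new_counts),
        binned_meta,
    )


def filter_open_ocean(meta: pd.DataFrame, min_seafloor_m: float = 200.0) -> pd.DataFrame:
    """Drop samples over shallow seafloor (strictly < threshold); missing
    seafloor depth also drops the sample, with a warning."""
    depth = pd.to_numeric(meta["seafloor_depth_m"], errors="coerce")
    missing = depth.isna()
    if missing.any():
        logger.warning(
            "filter_open_ocean: %d samples dropped for missing seafloor depth",
            int(missing.sum()),
        )
    keep = (~missing) & (depth >= min_seafloor_m)
    logger.info(
        "filter_open_ocean: removed %d of %d samples (< %g m)",
        int((~keep).sum()), len(meta), min_seafloor_m,
    )
    return meta.loc[keep].reset_index(drop=True)


def haversine_km(a, b) -> float:
    """Great-circle distance in km between (lat, lon) points, R = 6371 km."""
    lat1, lon1 = np.radians(np.asarray(a, dtype=float).T)
    lat2, lon2 = np.radians(np.asarray(b, dtype=float).T)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if np.ndim(d) == 0 else d


def pairwise_haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix for arrays of latitudes/longitudes."""
    latr = np.radians(np.asarray(lat, dtype=float))
    lonr = np.radians(np.asarray(lon, dtype=float))
    dlat = latr[:, None] - latr[None, :]
    dlon = lonr[:, None] - lonr[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(latr)[:, None] * np.cos(latr)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def thin_spatial(meta: pd.DataFrame, min_km: float, seed: int) -> pd.DataFrame:
    """Greedy spatial thinning: repeatedly remove the sample with the most
    neighbors closer than ``min_km`` (seeded random tie-break) until every
    retained pair is at least ``min_km`` apart."""
    if len(meta) == 0:
        raise ValueError("thin_spatial requires at least one sample")
    rng = np.random.default_rng(seed)
    dist = pairwise_haversine_km(
        meta["latitude"].to_numpy(dtype=float),
        meta["longitude"].to_numpy(dtype=float),
    )
    close = dist < min_km
    np.fill_diagonal(close, False)
    alive = np.ones(len(meta), dtype=bool)
    while True:
        neighbor_counts = (close & alive[None, :]).sum(axis=1)
        neighbor_counts[~alive] = 0
        worst = neighbor_counts.max()
        if worst == 0:
            break
        candidates = np.flatnonzero(alive & (neighbor_counts == worst))
        victim = int(rng.choice(candidates))
        alive[victim] = False
    logger.info(
        "thin_spatial: retained %d of %d samples (min %g km)",
        int(alive.sum()), len(meta), min_km,
    )
    return meta.loc[alive].reset_index(drop=True)


def filter_otus(
    table: OtuTable,
    min_frac: float = 0.002,
    min_prevalence: float = 0.10,
    depth: float | None = None,
) -> OtuTable:
    """Keep OTUs reaching ``min_frac`` of the per-sample depth in at least
    ``ceil(min_prevalence * n_samples)`` samples.

    The per-sample read threshold is ``min_frac * depth`` and a sample counts
    as an occurrence when its value is >= that threshold (with depth 10,000
    and min_frac 0.002 the threshold is 20 reads). ``depth`` defaults to the
    maximum row sum, correct for rarefied (and then averaged) tables.
    """
    if table.n_samples == 0:
        return table
    if depth is None:
        depth = float(table.counts.sum(axis=1).max())
    threshold = min_frac * depth
    need = int(np.ceil(min_prevalence * table.n_samples))
    prevalence = ((table.counts >= threshold) & (table.counts > 0)).sum(axis=0)
    keep = prevalence >= max(need, 1)
    logger.info(
        "filter_otus: kept %d of %d OTUs (>= %g reads in >= %d samples)",
        int(keep.sum()), table.n_otus, threshold, need,
    )
    return OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
        counts=table.counts[:, keep],
    )


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform: per row, ln(x + pseudocount) minus the
    row mean of the logs. Rows of the result sum to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(np.asarray(table.counts, dtype=float) + pseudocount)
    values = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        values=values,
    )


def subset_table(table: OtuTable, sample_ids: list[str]) -> OtuTable:
    """Restrict a table to the given samples, preserving the given order."""
    index = {s: i for i, s in enumerate(table.sample_ids)}
    rows = [index[s] for s in sample_ids]
    return OtuTable(
        sample_ids=list(sample_ids),
        otu_ids=list(table.otu_ids),
        counts=table.counts[rows],
    )
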