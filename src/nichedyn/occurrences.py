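"""Occurrence cleaning, inclusion filters, and background assignment.

An occurrence table is a pandas DataFrame with columns
``species, longitude, latitude, status`` (``status`` in {native, alien})
plus an optional ``provenance`` tag.  Backgrounds are built per range as the
union of all regions (ecoregion stand-ins) holding at least one occurrence
of the species, with climate values attached per background cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import ClimateLayerSet, RegionMap

__all__ = [
    "REQUIRED_COLUMNS",
    "STATUSES",
    "DEFAULT_THINNING_RADIUS",
    "MIN_OCCURRENCES",
    "BackgroundSet",
    "read_occurrences",
    "write_occurrences",
    "disaggregate",
    "meets_minimum",
    "filter_min_occurrences",
    "assign_background",
    "screen_variable_correlations",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "longitude", "latitude", "status")
STATUSES = ("native", "alien")
#: thinning radius in degrees of arc (~9.3 km at the equator)
DEFAULT_THINNING_RADIUS = 0.08333
#: minimum records per range for a species to enter the analysis
MIN_OCCURRENCES = 40


def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table lacks required columns: {missing}")
    bad_status = set(occ["status"].unique()) - set(STATUSES)
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    lon = occ["longitude"].to_numpy(float)
    lat = occ["latitude"].to_numpy(float)
    if ((lon < -180) | (lon > 180)).any() or ((lat < -90) | (lat > 90)).any():
        raise ValueError("coordinates outside [-180, 180] x [-90, 90]")
    return occ


def read_occurrences(path: str | Path) -> pd.DataFrame:
    occ = pd.read_csv(path)
    return validate_occurrences(occ)


def write_occurrences(occ: pd.DataFrame, path: str | Path) -> None:
    validate_occurrences(occ)
    occ.to_csv(path, index=False)


def _unit_vectors(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def disaggregate(
    occ: pd.DataFrame,
    radius: float = DEFAULT_THINNING_RADIUS,
    seed: int | None = 0,
    metric: str = "haversine",
) -> pd.DataFrame:
    """Spatially thin clustered occurrence points.

    Greedy sequential thinning in random order, independently per species and
    status: points are visited in shuffled order and kept iff no already-kept
    point lies within ``radius``.  With ``metric="haversine"`` the radius is
    interpreted as degrees of great-circle arc; ``metric="planar"`` treats
    lon/lat as a flat plane (appropriate for synthetic landscapes).

    The result is a subset of the input; no two retained points of the same
    species and status are within the radius, so the operation is idempotent.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if metric not in ("haversine", "planar"):
        raise ValueError(f"unknown metric {metric!r}")
    if occ.empty:
        return occ.copy()
    validate_occurrences(occ)
    rng = np.random.default_rng(seed)

    kept_parts = []
    for _, group in occ.groupby(["species", "status"], sort=False):
        lon = group["longitude"].to_numpy(float)
        lat = group["latitude"].to_numpy(float)
        if metric == "haversine":
            pts = _unit_vectors(lon, lat)
            r = 2.0 * np.sin(np.radians(radius) / 2.0)  # chord length
        else:
            pts = np.column_stack([lon, lat])
            r = radius
        tree = cKDTree(pts)
        neighbors = tree.query_ball_point(pts, r)
        order = rng.permutation(len(group))
        kept = np.zeros(len(group), dtype=bool)
        blocked = np.zeros(len(group), dtype=bool)
        for i in order:
            if blocked[i]:
                continue
            kept[i] = True
            blocked[neighbors[i]] = True
        kept_parts.append(group.iloc[np.flatnonzero(kept)])
    out = pd.concat(kept_parts).sort_index()
    return out


def meets_minimum(occ: pd.DataFrame, minimum: int = MIN_OCCURRENCES) -> bool:
    """Keep decision for one species: >= ``minimum`` records in *both* ranges."""
    counts = occ["status"].value_counts()
    return all(counts.get(s, 0) >= minimum for s in STATUSES)


def filter_min_occurrences(
    occ: pd.DataFrame, minimum: int = MIN_OCCURRENCES
) -> pd.DataFrame:
    """Drop every species lacking ``minimum`` records in either range."""
    keep = occ.groupby("species")["status"].transform(
        lambda s: all((s == st).sum() >= minimum for st in STATUSES)
    )
    return occ[keep.astype(bool)].copy()


@dataclass
class BackgroundSet:
    """Background cells (region-union) and their climate, per range."""

    cells: dict[str, pd.DataFrame]  # status -> DataFrame(row, col, lon, lat, <vars>)
    region_ids: dict[str, np.ndarray]
    n_dropped: int = 0

    def climate(self, status: str, variables: Iterable[str]) -> pd.DataFrame:
        return self.cells[status][list(variables)]

    def pooled_climate(self, variables: Iterable[str]) -> pd.DataFrame:
        return pd.concat(
            [self.climate(s, variables) for s in STATUSES], ignore_index=True
        )


def assign_background(
    occ: pd.DataFrame,
    regions: RegionMap,
    climate: ClimateLayerSet,
) -> tuple[pd.DataFrame, BackgroundSet]:
    """Attach grid cells to occurrences and build per-range backgrounds.

    The background of a range is the union of the cells of every region that
    contains at least one occurrence of that range.  Occurrences falling
    outside the mapped extent are dropped with a log entry.  Returns the
    (possibly reduced) occurrence table with ``row``/``col`` columns added,
    plus the BackgroundSet.
    """
    validate_occurrences(occ)
    geom = regions.geometry
    row, col = geom.cell_of(occ["longitude"].to_numpy(), occ["latitude"].to_numpy())
    inside = row >= 0
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning(
            "dropping %d occurrence(s) outside the mapped extent", n_dropped
        )
    occ = occ.loc[inside].copy()
    occ["row"], occ["col"] = row[inside], col[inside]

    cells: dict[str, pd.DataFrame] = {}
    rids: dict[str, np.ndarray] = {}
    for status in STATUSES:
        sub = occ[occ["status"] == status]
        if sub.empty:
            raise ValueError(f"no occurrences left in the {status} range")
        occupied = np.unique(regions.labels[sub["row"], sub["col"]])
        rids[status] = occupied
        mask = np.isin(regions.labels, occupied)
        r, c = np.nonzero(mask)
        tab = pd.DataFrame(
            {
                "row": r,
                "col": c,
                "longitude": geom.x_centers[c],
                "latitude": geom.y_centers[r],
            }
        )
        cells[status] = pd.concat(
            [tab, climate.values_at(r, c)], axis=1
        )
    return occ, BackgroundSet(cells=cells, region_ids=rids, n_dropped=n_dropped)


def screen_variable_correlations(
    values: pd.DataFrame, threshold: float = 0.8
) -> list[tuple[str, str, float]]:
    """Report variable pairs with |Pearson r| >= threshold (advisory only).

    Zero-variance variables make the coefficient undefined; their pairs are
    reported with ``r = nan``.
    """
    cols = list(values.columns)
    if len(cols) < 2 or len(values) < 3:
        raise ValueError("need >= 2 variables and >= 3 cells")
    x = values.to_numpy(float)
    sd = x.std(axis=0)
    offending = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if sd[i] == 0 or sd[j] == 0:
                offending.append((cols[i], cols[j], float("nan")))
                continue
            r = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
            if abs(r) >= threshold:
                offending.append((cols[i], cols[j], r))
    return offending
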