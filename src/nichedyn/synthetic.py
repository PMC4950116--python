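"""Virtual landscapes, climate layers, region mosaics and virtual species.

Everything downstream of this module is testable against known ground
truth: climate layers are spatially autocorrelated Gaussian random fields
with controllable cross-variable correlation, regions are a Voronoi mosaic
(a stand-in for an ecoregion map), and virtual species draw occurrences
from Gaussian suitability in climate space with a known niche optimum,
covariance, alien shift, alien breadth factor and geographic unfilling.

Variables follow the bioclim naming convention:

========  =======================================  ========
variable  meaning                                  units
========  =======================================  ========
bio5      maximum temperature of warmest month     °C
bio6      minimum temperature of coldest month     °C
bio7      temperature annual range (bio5 - bio6)   °C
bio9      mean temperature of driest quarter       °C
bio15     precipitation seasonality                unitless
wbal      annual water balance, Σ(prec_m - PET_m)  mm
========  =======================================  ========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grids import GridGeometry

__all__ = [
    "BASE_VARIABLES",
    "VARIABLES",
    "ClimateLayerSet",
    "RegionMap",
    "VirtualSpeciesSpec",
    "default_cross_correlation",
    "generate_landscape",
    "compute_wbal",
    "sample_virtual_species",
]

#: variables generated as (correlated) random fields
BASE_VARIABLES: tuple[str, ...] = ("bio5", "bio6", "bio9", "bio15", "wbal")
#: full variable set; bio7 is derived as bio5 - bio6
VARIABLES: tuple[str, ...] = ("bio5", "bio6", "bio7", "bio9", "bio15", "wbal")

# landscape-scale mean and spatial standard deviation per variable, chosen to
# span realistic warm-temperate to tropical conditions
_VARIABLE_SCALES: dict[str, tuple[float, float]] = {
    "bio5": (26.0, 6.0),
    "bio6": (2.0, 8.0),
    "bio9": (12.0, 7.0),
    "bio15": (45.0, 25.0),
    "wbal": (150.0, 250.0),
}

# annual water balance is clipped so that the consistent monthly
# precipitation stacks (prec_m = PET_m + wbal/12, PET_m >= 45) stay positive
_WBAL_FLOOR = -460.0


def default_cross_correlation() -> np.ndarray:
    """Moderate, realistic correlation structure among the base variables.

    Temperature variables (bio5, bio6, bio9) form a correlated block and the
    water variables (bio15, wbal) are weakly coupled to them, emulating the
    coarse structure of global bioclim layers without reproducing any
    particular data set.
    """
    corr = np.array(
        [
            # bio5   bio6   bio9  bio15   wbal
            [1.00, 0.55, 0.50, 0.20, -0.30],
            [0.55, 1.00, 0.70, 0.10, 0.05],
            [0.50, 0.70, 1.00, 0.05, 0.00],
            [0.20, 0.10, 0.05, 1.00, -0.35],
            [-0.30, 0.05, 0.00, -0.35, 1.00],
        ]
    )
    return corr


@dataclass
class ClimateLayerSet:
    """A stack of climate grids sharing one geometry."""

    geometry: GridGeometry
    layers: dict[str, np.ndarray]
    monthly_precipitation: np.ndarray | None = None  # (12, nrows, ncols), mm
    monthly_pet: np.ndarray | None = None  # (12, nrows, ncols), mm

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def values_at(self, rows, cols, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Climate values at grid cells as a DataFrame (one column per variable)."""
        variables = tuple(variables) if variables is not None else self.variables
        return pd.DataFrame(
            {v: self.layers[v][np.asarray(rows), np.asarray(cols)] for v in variables}
        )

    def table(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """All cells as rows (row-major order) with row/col/lon/lat columns."""
        nr, nc = self.geometry.shape
        rows, cols = np.indices((nr, nc))
        rows, cols = rows.ravel(), cols.ravel()
        out = pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "longitude": self.geometry.x_centers[cols],
                "latitude": self.geometry.y_centers[rows],
            }
        )
        return pd.concat([out, self.values_at(rows, cols, variables)], axis=1)


@dataclass
class RegionMap:
    """Integer region labels on the climate grid (ecoregion-mosaic stand-in)."""

    geometry: GridGeometry
    labels: np.ndarray

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class VirtualSpeciesSpec:
    """Ground-truth niche of a virtual species.

    The niche is Gaussian in *standardized* raw climate space (per-variable
    z-scores over the landscape), not in PCA space, so the pipeline's own
    ordination is exercised honestly.  ``center`` and ``covariance`` refer to
    the native range; the alien niche is centred at ``center + shift`` with
    covariance scaled by ``breadth_factor**2``.
    """

    name: str
    variables: tuple[str, ...] = BASE_VARIABLES
    center: np.ndarray | Sequence[float] | None = None
    covariance: np.ndarray | None = None
    shift: np.ndarray | Sequence[float] | None = None
    breadth_factor: float = 1.0
    n_native: int = 300
    n_alien: int = 300
    unfilled_mask: np.ndarray | None = None  # bool grid; alien cells withheld
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.variables)
        self.center = np.zeros(k) if self.center is None else np.asarray(self.center, float)
        self.shift = np.zeros(k) if self.shift is None else np.asarray(self.shift, float)
        if self.covariance is None:
            self.covariance = np.eye(k) * 0.6**2
        self.covariance = np.asarray(self.covariance, float)
        if self.center.shape != (k,) or self.shift.shape != (k,):
            raise ValueError("center/shift length must match the variable list")
        if self.covariance.shape != (k, k):
            raise ValueError("covariance shape must match the variable list")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() <= 0:
            raise ValueError("niche covariance must be positive definite")
        if self.breadth_factor <= 0:
            raise ValueError("breadth_factor must be > 0")
        if self.n_native < 1 or self.n_alien < 1:
            raise ValueError("n_native and n_alien must be >= 1")

    def ground_truth(self) -> dict:
        return {
            "name": self.name,
            "variables": list(self.variables),
            "center": np.asarray(self.center).tolist(),
            "covariance": np.asarray(self.covariance).tolist(),
            "shift": np.asarray(self.shift).tolist(),
            "breadth_factor": float(self.breadth_factor),
            "n_native": int(self.n_native),
            "n_alien": int(self.n_alien),
            "seed": int(self.seed),
        }


def _check_correlation_matrix(corr: np.ndarray, k: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    return corr


def _standardize_field(f: np.ndarray) -> np.ndarray:
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f - f.mean()


def generate_landscape(
    seed: int,
    geometry: GridGeometry,
    autocorrelation_range: float = 4.0,
    cross_correlation: np.ndarray | None = None,
    n_regions: int = 20,
    include_monthly: bool = False,
) -> tuple[ClimateLayerSet, RegionMap]:
    """Generate correlated, spatially autocorrelated climate layers + regions.

    Random fields are built by Gaussian-smoothing white noise
    (``autocorrelation_range`` is the smoothing sigma in cells; 0 gives
    spatially independent cells), standardizing, and mixing with the matrix
    square root of ``cross_correlation`` so that cross-variable correlations
    approximately match the request.  Regions are the Voronoi mosaic of
    ``n_regions`` random seed cells.
    """
    if cross_correlation is None:
        cross_correlation = np.eye(len(BASE_VARIABLES))
    corr = _check_correlation_matrix(cross_correlation, len(BASE_VARIABLES))
    if n_regions < 2:
        raise ValueError("need at least 2 regions")

    rng = np.random.default_rng(seed)
    nr, nc = geometry.shape
    noise = rng.standard_normal((len(BASE_VARIABLES), nr, nc))
    if autocorrelation_range > 0:
        noise = np.stack([gaussian_filter(f, autocorrelation_range) for f in noise])
    fields = np.stack([_standardize_field(f) for f in noise])

    # matrix square root via eigendecomposition (tolerates a singular corr)
    w, v = np.linalg.eigh(corr)
    mix = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    mixed = np.einsum("ij,jrc->irc", mix, fields)

    layers: dict[str, np.ndarray] = {}
    for i, var in enumerate(BASE_VARIABLES):
        mean, sd = _VARIABLE_SCALES[var]
        layer = mean + sd * mixed[i]
        if var == "wbal":
            layer = np.clip(layer, _WBAL_FLOOR, None)
        layers[var] = layer
    layers["bio7"] = layers["bio5"] - layers["bio6"]
    layers = {v: layers[v] for v in VARIABLES}

    monthly_prec = monthly_pet = None
    if include_monthly:
        # seasonal PET cycle (mm/month) plus precipitation chosen so that the
        # monthly stacks sum exactly to the generated annual water balance
        months = np.arange(12)
        pet_cycle = 45.0 + 25.0 * (1.0 + np.sin(2.0 * np.pi * months / 12.0)) / 2.0
        monthly_pet = np.broadcast_to(
            pet_cycle[:, None, None], (12, nr, nc)
        ).copy()
        monthly_prec = monthly_pet + layers["wbal"][None, :, :] / 12.0

    ly = ClimateLayerSet(
        geometry=geometry,
        layers=layers,
        monthly_precipitation=monthly_prec,
        monthly_pet=monthly_pet,
    )

    # Voronoi mosaic: nearest random seed cell in (row, col) space
    seeds = np.column_stack(
        [rng.uniform(0, nr, size=n_regions), rng.uniform(0, nc, size=n_regions)]
    )
    rows, cols = np.indices((nr, nc))
    pts = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(pts)
    regions = RegionMap(geometry=geometry, labels=nearest.reshape(nr, nc).astype(int))
    return ly, regions


def compute_wbal(monthly_precipitation: np.ndarray, monthly_pet: np.ndarray) -> np.ndarray:
    """Annual water balance: per cell, Σ over 12 months of (prec_m - PET_m)."""
    prec = np.asarray(monthly_precipitation, dtype=float)
    pet = np.asarray(monthly_pet, dtype=float)
    if prec.shape != pet.shape:
        raise ValueError(
            f"precipitation stack {prec.shape} and PET stack {pet.shape} differ in geometry"
        )
    if prec.shape[0] != 12:
        raise ValueError("monthly stacks must have 12 layers along the first axis")
    return (prec - pet).sum(axis=0)


def landscape_standardization(
    climate: ClimateLayerSet, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable mean and SD over all landscape cells (z-score reference)."""
    means = np.array([climate.layers[v].mean() for v in variables])
    sds = np.array([climate.layers[v].std() for v in variables])
    return means, sds


def _suitability(
    climate: ClimateLayerSet,
    mask: np.ndarray,
    variables: Sequence[str],
    center: np.ndarray,
    cov: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian suitability at the cells of ``mask`` (z-scored climate space)."""
    means, sds = landscape_standardization(climate, variables)
    rows, cols = np.nonzero(mask)
    x = np.column_stack(
        [(climate.layers[v][rows, cols] - means[i]) / sds[i] for i, v in enumerate(variables)]
    )
    d = x - center
    prec = np.linalg.inv(cov)
    maha = np.einsum("ni,ij,nj->n", d, prec, d)
    return rows, cols, np.exp(-0.5 * maha)


def sample_virtual_species(
    spec: VirtualSpeciesSpec,
    climate: ClimateLayerSet,
    native_mask: np.ndarray,
    alien_mask: np.ndarray,
) -> pd.DataFrame:
    """Draw native and alien occurrences of a virtual species.

    Cells are sampled (with replacement) with probability proportional to the
    Gaussian suitability of their climate; points are jittered uniformly
    within the cell.  Alien cells under ``spec.unfilled_mask`` get zero
    sampling probability, imposing geographic unfilling.  The returned
    DataFrame has columns ``species, longitude, latitude, status, provenance``
    and carries ``spec.ground_truth()`` in ``.attrs["ground_truth"]``.
    """
    native_mask = np.asarray(native_mask, bool)
    alien_mask = np.asarray(alien_mask, bool)
    if native_mask.shape != climate.geometry.shape or alien_mask.shape != native_mask.shape:
        raise ValueError("masks must match the climate grid shape")
    if (native_mask & alien_mask).any():
        raise ValueError("native and alien masks must be disjoint")

    rng = np.random.default_rng(spec.seed)
    geom = climate.geometry
    frames = []
    ranges = {
        "native": (native_mask, spec.center, spec.covariance, spec.n_native, None),
        "alien": (
            alien_mask,
            np.asarray(spec.center) + np.asarray(spec.shift),
            np.asarray(spec.covariance) * spec.breadth_factor**2,
            spec.n_alien,
            spec.unfilled_mask,
        ),
    }
    for status, (mask, center, cov, n, withheld) in ranges.items():
        rows, cols, suit = _suitability(climate, mask, spec.variables, center, cov)
        if withheld is not None:
            suit = np.where(np.asarray(withheld, bool)[rows, cols], 0.0, suit)
        total = suit.sum()
        if rows.size == 0 or total <= 0:
            raise ValueError(
                f"all-zero suitability in the {status} range of species {spec.name!r}"
            )
        idx = rng.choice(rows.size, size=n, replace=True, p=suit / total)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * geom.cell_size
        frames.append(
            pd.DataFrame(
                {
                    "species": spec.name,
                    "longitude": geom.x_centers[cols[idx]] + jitter[:, 0],
                    "latitude": geom.y_centers[rows[idx]] + jitter[:, 1],
                    "status": status,
                    "provenance": "virtual",
                }
            )
        )
    occ = pd.concat(frames, ignore_index=True)
    occ.attrs["ground_truth"] = spec.ground_truth()
    return occ
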