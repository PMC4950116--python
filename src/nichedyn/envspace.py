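"""Two-axis environmental ordination (PCA-env) and gridded niche surfaces.

The ordination is a PCA of the standardized climate of the *pooled* native
and alien backgrounds of one species.  Its first two axes span an R x R
grid (default 100 x 100) of environmental space; occurrences and background
cells become kernel-smoothed densities (``o`` and ``e``) on that grid, and
the density-corrected realized niche is the occupancy

    z_ij = o_ij / e_ij   where e_ij > eps, else 0,   normalized to unit sum.

Kernel smoothing is a binned Gaussian product kernel: points are counted on
the grid and convolved with a Gaussian whose per-axis bandwidth follows a
Silverman-type rule, h_i = sigma_i * n^(-1/6).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA

__all__ = [
    "EnvSpace",
    "NicheGrid",
    "fit_pca_env",
    "grid_env_space",
    "density_surface",
    "occupancy",
    "build_niche_grid",
    "silverman_bandwidth",
]

#: availability below EPS_REL * max(e) counts as "environment not available"
EPS_REL = 1e-10
DEFAULT_R = 100
DEFAULT_MARGIN = 0.05


@dataclass
class EnvSpace:
    """Fitted two-axis ordination plus the environmental grid geometry."""

    variables: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (2, n_vars), rows orthonormal
    explained_variance_ratio: np.ndarray  # (2,)
    score_range: np.ndarray  # (2, 2): per axis (min, max) of training scores
    R: int
    margin: float
    x_edges: np.ndarray  # (R+1,)
    y_edges: np.ndarray  # (R+1,)

    def transform(self, values: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project climate values onto the two ordination axes."""
        if isinstance(values, pd.DataFrame):
            values = values[list(self.variables)].to_numpy(float)
        x = (np.asarray(values, float) - self.means) / self.sds
        return x @ self.loadings.T

    @property
    def cell_widths(self) -> tuple[float, float]:
        return (
            float(self.x_edges[1] - self.x_edges[0]),
            float(self.y_edges[1] - self.y_edges[0]),
        )

    @property
    def cell_area(self) -> float:
        wx, wy = self.cell_widths
        return wx * wy

    def axis_centers(self, axis: int) -> np.ndarray:
        edges = self.x_edges if axis == 0 else self.y_edges
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class NicheGrid:
    """Occurrence density o, availability e and occupancy z for one range."""

    status: str
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    n_occurrences: int
    n_background: int


def fit_pca_env(
    background_values: pd.DataFrame,
    R: int = DEFAULT_R,
    margin: float = DEFAULT_MARGIN,
) -> EnvSpace:
    """Fit the ordination on pooled background climate (both ranges).

    Variables are standardized to zero mean / unit variance before the PCA;
    the first two components are kept.  Axis orientation is made
    reproducible by flipping each loading vector so its largest-magnitude
    entry is positive.
    """
    if len(background_values) < 3:
        raise ValueError("need at least 3 background cells")
    variables = tuple(background_values.columns)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    x = background_values.to_numpy(float)
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    constant = [v for v, s in zip(variables, sds) if s == 0]
    if constant:
        raise ValueError(f"constant variable(s) in background climate: {constant}")
    xs = (x - means) / sds

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(xs)
    loadings = pca.components_.copy()
    for a in range(2):
        if loadings[a, np.argmax(np.abs(loadings[a]))] < 0:
            loadings[a] = -loadings[a]
            scores[:, a] = -scores[:, a]

    score_range = np.column_stack([scores.min(axis=0), scores.max(axis=0)])
    env = EnvSpace(
        variables=variables,
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_[:2].copy(),
        score_range=score_range,
        R=R,
        margin=margin,
        x_edges=np.empty(0),
        y_edges=np.empty(0),
    )
    return grid_env_space(env, R)


def grid_env_space(env: EnvSpace, R: int = DEFAULT_R) -> EnvSpace:
    """Lay an R x R grid over the training score range (plus a margin).

    Returns a new EnvSpace; the input is left untouched.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    edges = []
    for axis in range(2):
        lo, hi = env.score_range[axis]
        if hi <= lo:
            raise ValueError(f"degenerate score range on axis {axis + 1}")
        pad = env.margin * (hi - lo)
        edges.append(np.linspace(lo - pad, hi + pad, R + 1))
    return replace(env, R=R, x_edges=edges[0], y_edges=edges[1])


def silverman_bandwidth(scores: np.ndarray) -> np.ndarray:
    """Per-axis rule-of-thumb bandwidth for a 2-D Gaussian product kernel."""
    scores = np.atleast_2d(np.asarray(scores, float))
    n = scores.shape[0]
    return scores.std(axis=0) * n ** (-1.0 / 6.0)


def density_surface(
    scores: np.ndarray,
    env: EnvSpace,
    bandwidth: np.ndarray | tuple[float, float] | None = None,
) -> np.ndarray:
    """Kernel-smoothed density of points on the environmental grid.

    Returns an (R, R) array indexed [axis-1 bin, axis-2 bin] whose cell sum
    times the cell area equals 1.  ``bandwidth`` overrides the Silverman
    rule; it is given in axis units.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] < 1:
        raise ValueError("need at least one point")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(scores)
    bandwidth = np.asarray(bandwidth, float)
    if np.any(bandwidth <= 0):
        raise ValueError("kernel bandwidth must be positive on both axes")

    # clip scores into the grid so no point loses all its mass
    x = np.clip(scores[:, 0], env.x_edges[0], env.x_edges[-1])
    y = np.clip(scores[:, 1], env.y_edges[0], env.y_edges[-1])
    counts, _, _ = np.histogram2d(x, y, bins=[env.x_edges, env.y_edges])
    wx, wy = env.cell_widths
    dens = gaussian_filter(counts, sigma=(bandwidth[0] / wx, bandwidth[1] / wy))
    total = dens.sum() * env.cell_area
    if total <= 0:
        raise ValueError("density surface has no mass")
    return dens / total


def occupancy(o: np.ndarray, e: np.ndarray, eps_rel: float = EPS_REL) -> np.ndarray:
    """Occurrence density scaled by environmental availability, unit-sum."""
    o = np.asarray(o, float)
    e = np.asarray(e, float)
    if o.shape != e.shape:
        raise ValueError(f"o and e must share a grid; got {o.shape} vs {e.shape}")
    emax = e.max()
    if emax <= 0:
        raise ValueError("availability density is identically zero")
    eps = eps_rel * emax
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e > eps, o / np.where(e > eps, e, 1.0), 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy has no mass inside the available environment")
    return z / total


def build_niche_grid(
    env: EnvSpace,
    occurrence_scores: np.ndarray,
    background_scores: np.ndarray,
    status: str,
    bandwidth=None,
) -> NicheGrid:
    """Convenience: o from occurrences, e from background cells, z = o/e."""
    o = density_surface(occurrence_scores, env, bandwidth=bandwidth)
    e = density_surface(background_scores, env, bandwidth=bandwidth)
    z = occupancy(o, e)
    return NicheGrid(
        status=status,
        o=o,
        e=e,
        z=z,
        n_occurrences=int(np.atleast_2d(occurrence_scores).shape[0]),
        n_background=int(np.atleast_2d(background_scores).shape[0]),
    )


def occupancy_marginal(z: np.ndarray, env: EnvSpace, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Marginal occupancy mass along one ordination axis (coords, weights)."""
    coords = env.axis_centers(axis)
    weights = z.sum(axis=1 - axis)
    return coords, weights


def weighted_quantile(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    """Quantiles of a discrete weighted sample (cumulative-mass inversion)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    if cum[-1] <= 0:
        raise ValueError("weights sum to zero")
    cum = cum / cum[-1]
    return np.interp(np.atleast_1d(qs), cum, v)


def niche_breadth_from_occupancy(z: np.ndarray, env: EnvSpace) -> np.ndarray:
    """Per-axis niche breadth: central-95% span of the occupancy marginal."""
    out = []
    for axis in range(2):
        coords, w = occupancy_marginal(z, env, axis)
        lo, hi = weighted_quantile(coords, w, [0.025, 0.975])
        out.append(hi - lo)
    return np.array(out)
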