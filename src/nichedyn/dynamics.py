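"""Niche-change inference: bootstrap optimum/breadth, expansion/unfilling,
and scenario classification.

Bootstrap
---------
Occurrence records of each range are resampled with replacement B times
(default 100).  Per replicate the ordination is refit (the backgrounds stay
fixed by default, so the refit is deterministic), densities are rebuilt, and
P grid pixels per range (default 100) are drawn with probability
proportional to occupancy.  Per axis, the niche optimum is the median of
the P pixel coordinates and the niche breadth their 0.975-0.025 quantile
span.  A shift Δ = optimum_native - optimum_alien and a breadth ratio
r = breadth_alien / breadth_native are recorded per replicate; significance
uses the central 95% of the B values (shift: interval excludes 0; breadth:
interval entirely below/above 1).

Decomposition
-------------
Expansion E is the alien occupancy mass outside the native niche extent,
stability S = 1 - E, and unfilling U the native occupancy mass outside the
alien extent.  "Analogous" mode first restricts all surfaces to the
environments available in both backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .envspace import (
    EPS_REL,
    DEFAULT_R,
    EnvSpace,
    density_surface,
    fit_pca_env,
    grid_env_space,
    occupancy,
)

__all__ = [
    "NicheChangeEstimate",
    "DynamicsDecomposition",
    "ScenarioLabel",
    "bootstrap_niche_metrics",
    "expansion_unfilling",
    "classify_scenario",
]

BREADTH_STATES = ("broadened", "contracted", "unchanged")


@dataclass
class NicheChangeEstimate:
    """Bootstrap distributions and significance flags for one species."""

    shifts: np.ndarray  # (2, B): Δ per axis, native optimum - alien optimum
    breadth_ratios: np.ndarray  # (2, B): alien breadth / native breadth
    optima: dict  # status -> (2, B)
    breadths: dict  # status -> (2, B)
    shift_interval: np.ndarray  # (2, 2)
    ratio_interval: np.ndarray  # (2, 2)
    shift_significant: tuple[bool, bool]
    breadth_flags: tuple[str, str]  # per axis, one of BREADTH_STATES
    B: int
    P: int
    seed: int | None
    env: EnvSpace | None = None  # reference (full-data) ordination

    def mean_shift(self, axis: int) -> float:
        return float(self.shifts[axis].mean())

    def mean_breadth_ratio(self, axis: int) -> float:
        return float(self.breadth_ratios[axis].mean())

    def median_breadth_ratio(self, axis: int) -> float:
        return float(np.median(self.breadth_ratios[axis]))

    def mean_native_breadth(self, axis: int) -> float:
        return float(self.breadths["native"][axis].mean())


def _sample_pixels(
    z: np.ndarray, env: EnvSpace, P: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw P grid cells with probability ∝ occupancy; coords at cell centers."""
    flat = z.ravel()
    idx = rng.choice(flat.size, size=P, replace=True, p=flat / flat.sum())
    i, j = np.unravel_index(idx, z.shape)
    return np.column_stack([env.axis_centers(0)[i], env.axis_centers(1)[j]])


def _align_loadings(env: EnvSpace, reference: EnvSpace) -> EnvSpace:
    """Sign-flip axes to maximize agreement with the reference loadings."""
    for a in range(2):
        if np.dot(env.loadings[a], reference.loadings[a]) < 0:
            env.loadings[a] = -env.loadings[a]
            env.score_range[a] = -env.score_range[a, ::-1]
    return grid_env_space(env, env.R)


def bootstrap_niche_metrics(
    native_occ_values: pd.DataFrame,
    alien_occ_values: pd.DataFrame,
    native_background_values: pd.DataFrame,
    alien_background_values: pd.DataFrame,
    B: int = 100,
    P: int = 100,
    R: int = DEFAULT_R,
    seed: int | None = None,
    resample_background: bool = False,
) -> NicheChangeEstimate:
    """Bootstrap the per-axis niche optimum shift and breadth ratio.

    All four inputs are climate-value tables (rows = occurrences or
    background cells, columns = variables).  The ordination is calibrated on
    the pooled backgrounds; when ``resample_background`` is on, background
    cells are resampled alongside occurrences and each replicate's loadings
    are sign-aligned to the full-data reference before use.
    """
    if B < 2 or P < 2:
        raise ValueError("B and P must both be >= 2")
    if len(native_occ_values) == 0 or len(alien_occ_values) == 0:
        raise ValueError("both ranges need at least one occurrence")
    rng = np.random.default_rng(seed)

    occ = {"native": native_occ_values, "alien": alien_occ_values}
    bg = {"native": native_background_values, "alien": alien_background_values}
    pooled_bg = pd.concat([bg["native"], bg["alien"]], ignore_index=True)
    ref_env = fit_pca_env(pooled_bg, R=R)

    # fixed backgrounds make the per-replicate ordination refit deterministic,
    # so the fitted space and availability densities are computed once
    fixed_e = None
    if not resample_background:
        fixed_e = {
            s: density_surface(ref_env.transform(bg[s]), ref_env) for s in occ
        }

    optima = {s: np.empty((2, B)) for s in occ}
    breadths = {s: np.empty((2, B)) for s in occ}
    for b in range(B):
        if resample_background:
            bg_b = {
                s: v.iloc[rng.integers(0, len(v), len(v))] for s, v in bg.items()
            }
            env = fit_pca_env(
                pd.concat(list(bg_b.values()), ignore_index=True), R=R
            )
            env = _align_loadings(env, ref_env)
            e = {s: density_surface(env.transform(v), env) for s, v in bg_b.items()}
        else:
            env, e = ref_env, fixed_e
        for s, values in occ.items():
            take = rng.integers(0, len(values), len(values))
            scores = env.transform(values.iloc[take])
            z = occupancy(density_surface(scores, env), e[s])
            pix = _sample_pixels(z, env, P, rng)
            for axis in range(2):
                lo, med, hi = np.quantile(pix[:, axis], [0.025, 0.5, 0.975])
                optima[s][axis, b] = med
                # a degenerate all-one-cell draw cannot resolve breadth below
                # one grid cell
                breadths[s][axis, b] = max(hi - lo, env.cell_widths[axis])

    shifts = optima["native"] - optima["alien"]
    ratios = breadths["alien"] / breadths["native"]
    shift_iv = np.quantile(shifts, [0.025, 0.975], axis=1).T
    ratio_iv = np.quantile(ratios, [0.025, 0.975], axis=1).T
    shift_sig = tuple(bool(lo > 0 or hi < 0) for lo, hi in shift_iv)
    flags = []
    for lo, hi in ratio_iv:
        if lo > 1:
            flags.append("broadened")
        elif hi < 1:
            flags.append("contracted")
        else:
            flags.append("unchanged")
    return NicheChangeEstimate(
        shifts=shifts,
        breadth_ratios=ratios,
        optima=optima,
        breadths=breadths,
        shift_interval=shift_iv,
        ratio_interval=ratio_iv,
        shift_significant=shift_sig,
        breadth_flags=tuple(flags),
        B=B,
        P=P,
        seed=seed,
        env=ref_env,
    )


@dataclass
class DynamicsDecomposition:
    """Expansion / stability / unfilling shares of the niche comparison."""

    expansion: float
    stability: float
    unfilling: float
    mode: str = "full"
    extent_quantile: float = 1.0


def _extent(z: np.ndarray, quantile: float) -> np.ndarray:
    """Cells forming the niche extent (top-density cells holding ``quantile``
    of the total mass; 1.0 keeps the full observed support)."""
    if quantile >= 1.0:
        return z > 0
    flat = z.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, quantile * cum[-1])) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(z.shape)


def expansion_unfilling(
    z_native: np.ndarray,
    z_alien: np.ndarray,
    e_native: np.ndarray,
    e_alien: np.ndarray,
    mode: str = "full",
    extent_quantile: float = 1.0,
) -> DynamicsDecomposition:
    """Decompose the alien niche into expansion/stability and the native
    niche into filled/unfilled shares.

    ``mode="analogous"`` first restricts every surface to environments
    available in *both* backgrounds and renormalizes, separating genuine
    niche change from mere availability change.
    """
    if mode not in ("full", "analogous"):
        raise ValueError(f"unknown climate-space mode {mode!r}")
    zn = np.asarray(z_native, float)
    za = np.asarray(z_alien, float)
    if zn.shape != za.shape:
        raise ValueError("occupancy grids must share a shape")
    if mode == "analogous":
        en = np.asarray(e_native, float)
        ea = np.asarray(e_alien, float)
        avail = (en > EPS_REL * en.max()) & (ea > EPS_REL * ea.max())
        if not avail.any():
            raise ValueError("backgrounds share no analogous climates")
        zn, za = zn * avail, za * avail
        if zn.sum() <= 0 or za.sum() <= 0:
            raise ValueError("a niche has no mass inside the analogous climates")
        zn, za = zn / zn.sum(), za / za.sum()

    ext_native = _extent(zn, extent_quantile)
    ext_alien = _extent(za, extent_quantile)
    e_frac = float(za[~ext_native].sum() / za.sum())
    u_frac = float(zn[~ext_alien].sum() / zn.sum())
    return DynamicsDecomposition(
        expansion=e_frac,
        stability=1.0 - e_frac,
        unfilling=u_frac,
        mode=mode,
        extent_quantile=extent_quantile,
    )


@dataclass
class ScenarioLabel:
    """Niche-change scenario (A-F) with the >10% expansion/unfilling tags."""

    category: str  # 'A'..'F' or 'UNASSIGNED'
    annotation: tuple[str, ...] = ()

    @property
    def annotation_text(self) -> str:
        return " & ".join(self.annotation)


_SCENARIO_MAP = {
    (True, "contracted"): "A",
    (True, "unchanged"): "B",
    (True, "broadened"): "C",
    (False, "contracted"): "D",
    (False, "broadened"): "E",
    (False, "unchanged"): "F",
}


def classify_scenario(
    shift_significant: Sequence[bool],
    breadth_flags: Sequence[str],
    expansion: float,
    unfilling: float,
    threshold: float = 0.10,
) -> ScenarioLabel:
    """Map per-axis significance flags to a niche-change scenario.

    The optimum is taken to have shifted if significant on >= 1 axis; the
    niche counts as broadened (contracted) if significantly so on >= 1 axis
    with no significant change in the opposite direction.  Significant
    broadening on one axis together with significant contraction on the
    other leaves the species UNASSIGNED.  Expansion/unfilling above the
    threshold adds 'E'/'U' annotations.
    """
    for f in breadth_flags:
        if f not in BREADTH_STATES:
            raise ValueError(f"bad breadth flag {f!r}")
    shifted = any(bool(s) for s in shift_significant)
    broadened = "broadened" in breadth_flags
    contracted = "contracted" in breadth_flags
    annotation = tuple(
        tag for tag, value in (("E", expansion), ("U", unfilling)) if value > threshold
    )
    if broadened and contracted:
        return ScenarioLabel("UNASSIGNED", annotation)
    state = "broadened" if broadened else ("contracted" if contracted else "unchanged")
    return ScenarioLabel(_SCENARIO_MAP[(shifted, state)], annotation)
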