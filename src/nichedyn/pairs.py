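"""Paired sexual/apomictic comparison and predictors of niche expansion.

Differences are always sexual minus apomictic within a pair.  Tests use a
random-intercept linear mixed model (grouping by family for the pair-level
difference tests, by pair for the per-species expansion models); when the
grouping factor is singular — one observation per group, or a degenerate
variance component — the model reduces to ordinary least squares and the
reduction is logged.  Reported degrees of freedom follow the simple
fixed-effect convention df = n - 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAIR_METRICS",
    "MixedTestResult",
    "pair_differences",
    "test_mean_difference",
    "model_expansion",
]

logger = logging.getLogger(__name__)

#: per-species metrics differenced within each pair
PAIR_METRICS = (
    "d",
    "shift_pc1",
    "shift_pc2",
    "breadth_ratio_pc1",
    "breadth_ratio_pc2",
    "expansion",
    "unfilling",
)

REPRODUCTION_LABELS = ("sexual", "apomictic")


@dataclass
class MixedTestResult:
    estimate: float
    se: float
    t: float
    df: int
    p: float
    n: int
    reduced_to_ols: bool = False


def pair_differences(metrics: pd.DataFrame) -> pd.DataFrame:
    """Within-pair differences (sexual - apomictic) of niche-change metrics.

    ``metrics`` has one row per species with at least ``species``,
    ``pair_id``, ``family``, ``reproduction`` and the PAIR_METRICS columns
    that are present.  Every pair must contain exactly one species of each
    reproduction label; offenders are listed in the error.
    """
    required = {"species", "pair_id", "family", "reproduction"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    if metrics["species"].duplicated().any():
        dups = metrics.loc[metrics["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicated species rows: {dups}")
    bad = []
    for pid, grp in metrics.groupby("pair_id"):
        labels = sorted(grp["reproduction"])
        if labels != sorted(REPRODUCTION_LABELS):
            bad.append(pid)
    if bad:
        raise ValueError(f"pairs without exactly one sexual and one apomictic member: {bad}")

    cols = [c for c in PAIR_METRICS if c in metrics.columns]
    rows = []
    for pid, grp in metrics.groupby("pair_id"):
        sex = grp[grp["reproduction"] == "sexual"].iloc[0]
        apo = grp[grp["reproduction"] == "apomictic"].iloc[0]
        row = {"pair_id": pid, "family": sex["family"]}
        for c in cols:
            row[f"{c}_sexual"] = float(sex[c])
            row[f"{c}_apomictic"] = float(apo[c])
            row[f"{c}_diff"] = float(sex[c]) - float(apo[c])
        rows.append(row)
    return pd.DataFrame(rows).sort_values("pair_id").reset_index(drop=True)


def _fit_random_intercept(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """Random-intercept fit returning (params, bse, reduced_to_ols)."""
    import statsmodels.api as sm

    singleton_groups = pd.Series(groups).value_counts().max() == 1
    if not singleton_groups:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, x, groups=groups)
                fit = model.fit(reml=True)
            k = x.shape[1]
            params = np.asarray(fit.params)[:k]
            bse = np.asarray(fit.bse)[:k]
            if np.all(np.isfinite(bse)):
                return params, bse, False
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            pass
    logger.info("grouping factor singular; reducing to ordinary least squares")
    fit = sm.OLS(y, x).fit()
    return np.asarray(fit.params), np.asarray(fit.bse), True


def test_mean_difference(
    differences: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> MixedTestResult:
    """Does the mean within-pair difference deviate from zero?

    Random-intercept model of the differences on an intercept with the
    grouping factor (taxonomic family); degenerates to a one-sample t-test
    when every group holds a single pair.
    """
    y = np.asarray(differences, float)
    groups = np.asarray(groups)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if groups.size != n:
        raise ValueError("groups must match differences in length")
    df = n - 2
    if np.allclose(y, 0.0):
        return MixedTestResult(0.0, 0.0, 0.0, df, 1.0, n)
    x = np.ones((n, 1))
    params, bse, reduced = _fit_random_intercept(y, x, groups)
    est, se = float(params[0]), float(bse[0])
    t = est / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    return MixedTestResult(est, se, t, df, float(p), n, reduced)


def model_expansion(
    species_metrics: pd.DataFrame,
    predictor: str,
    response: str = "expansion",
) -> MixedTestResult:
    """Model a per-species niche metric on a predictor with pair grouping.

    ``predictor`` is either ``"reproduction"`` (coded sexual = 1,
    apomictic = 0) or the name of a numeric column such as
    ``"native_breadth"``.  Returns the slope coefficient and its test.
    """
    df_ = species_metrics
    if df_["species"].duplicated().any():
        raise ValueError("duplicated species rows")
    n = len(df_)
    if n < 6:
        raise ValueError("need at least 6 species (3 pairs)")
    y = df_[response].to_numpy(float)
    if predictor == "reproduction":
        xcol = (df_["reproduction"] == "sexual").to_numpy(float)
    else:
        xcol = df_[predictor].to_numpy(float)
    if np.ptp(xcol) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    x = np.column_stack([np.ones(n), xcol])
    params, bse, reduced = _fit_random_intercept(y, x, df_["pair_id"].to_numpy())
    est, se = float(params[1]), float(bse[1])
    dof = n - 2
    t = est / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), dof) if se > 0 else 1.0
    return MixedTestResult(est, se, t, dof, float(p), n, reduced)
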