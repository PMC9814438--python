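"""Threshold (re)calibration: Box-Cox transform and polynomial regression.

The threshold surface is derived from the Monte-Carlo reference
distribution of the criterion under no grey zone: over a grid of latent
correlations and sample sizes, the per-cell medians of kappa and Delta are
collected, the Delta medians are variance-stabilized with a Box-Cox power
transform (lambda by profile likelihood), and the transformed medians are
regressed on ``(1, kappa^2, n, n^2)`` by ordinary least squares — the model
is linear in its parameters.  Back-transforming the fitted surface yields
the threshold function ``tau(kappa, n)``.  Medians rather than means are
used throughout so that the heavy right tail of Delta (driven by replicates
with small kappa) cannot drag the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.stats import boxcox_llf

from .detection import ThresholdModel
from .exceptions import TableValidationError
from .simulation import summarize_replicates

__all__ = [
    "CalibrationDataset",
    "boxcox_lambda",
    "boxcox_transform",
    "inverse_boxcox",
    "calibration_grid",
    "fit_threshold_model",
    "model_search",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationDataset:
    """One row per (rho, n): the medians feeding the threshold regression."""

    frame: pd.DataFrame  # columns: rho, n, median_kappa, median_delta
    reps: int
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)


def boxcox_lambda(values: Sequence[float]) -> float:
    """Box-Cox power maximizing the profile log-likelihood on [-5, 5]."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise TableValidationError("need at least 3 values to estimate lambda")
    if np.any(x <= 0):
        raise TableValidationError("Box-Cox requires strictly positive values")
    res = optimize.minimize_scalar(
        lambda lam: -boxcox_llf(lam, x),
        bounds=(-5.0, 5.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def boxcox_transform(values, lambda_: float) -> np.ndarray:
    """``(v**lambda - 1)/lambda`` (log for lambda = 0)."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise TableValidationError("Box-Cox requires strictly positive values")
    if lambda_ == 0:
        return np.log(v)
    return (v**lambda_ - 1.0) / lambda_


def inverse_boxcox(values, lambda_: float) -> np.ndarray:
    """Inverse transform; raises outside the domain ``v*lambda + 1 > 0``."""
    v = np.asarray(values, dtype=float)
    if lambda_ == 0:
        return np.exp(v)
    base = v * lambda_ + 1.0
    if np.any(base <= 0):
        raise TableValidationError(
            "inverse Box-Cox undefined: v*lambda + 1 must be positive"
        )
    return base ** (1.0 / lambda_)


def calibration_grid(
    rho_set: Sequence[float],
    n_set: Sequence[int],
    reps: int,
    rng: np.random.Generator,
    R: int = 3,
    cutpoints=None,
) -> CalibrationDataset:
    """Monte-Carlo medians of (kappa, Delta) over a (rho, n) grid."""
    if reps < 2:
        raise TableValidationError("calibration needs reps >= 2 per grid cell")
    summary = summarize_replicates(rho_set, n_set, reps, rng, R=R, cutpoints=cutpoints)
    frame = summary.rename(
        columns={"kappa_med": "median_kappa", "delta_med": "median_delta"}
    )[["rho", "n", "median_kappa", "median_delta"]]
    keep = frame["median_delta"] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%d calibration cell(s) dropped: non-positive median Delta", n_dropped
        )
    return CalibrationDataset(frame=frame[keep].reset_index(drop=True),
                              reps=reps, n_dropped=n_dropped)


def _design(frame: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = {
        "kappa": frame["median_kappa"],
        "kappa2": frame["median_kappa"] ** 2,
        "n": frame["n"].astype(float),
        "n2": frame["n"].astype(float) ** 2,
    }
    X = np.column_stack([cols[t] for t in terms])
    return sm.add_constant(X)


def fit_threshold_model(
    data: CalibrationDataset, lambda_: float | None = None
) -> ThresholdModel:
    """Fit the threshold regression and return the resulting model.

    ``lambda_`` defaults to the profile-likelihood estimate on the median
    Delta values.  The regression is the fixed quadratic form
    ``Delta_BC ~ 1 + kappa^2 + n + n^2``.
    """
    frame = data.frame
    if len(frame) < 10:
        raise TableValidationError(
            "calibration needs >= 10 grid cells spanning kappa and n"
        )
    if frame["median_kappa"].nunique() < 2 or frame["n"].nunique() < 2:
        raise TableValidationError("degenerate grid: no variation in kappa or n")
    if lambda_ is None:
        lambda_ = boxcox_lambda(frame["median_delta"])
    y = boxcox_transform(frame["median_delta"], lambda_)
    X = _design(frame, ["kappa2", "n", "n2"])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise TableValidationError("rank-deficient calibration design")
    fit = sm.OLS(y, X).fit()
    k_lo = float(frame["median_kappa"].min())
    k_hi = float(frame["median_kappa"].max())
    return ThresholdModel(
        lambda_=float(lambda_),
        beta=tuple(float(b) for b in fit.params),
        source="refit",
        valid_n_range=(float(frame["n"].min()), float(frame["n"].max())),
        valid_kappa_range=(k_lo, k_hi),
        adj_r2=float(fit.rsquared_adj),
        pvalues=tuple(float(p) for p in fit.pvalues),
    )


def model_search(
    data: CalibrationDataset, lambda_: float | None = None
) -> pd.DataFrame:
    """Exhaustive adjusted-R^2 search over intercept + subsets of
    {kappa, kappa^2, n, n^2}, sorted best first."""
    frame = data.frame
    if lambda_ is None:
        lambda_ = boxcox_lambda(frame["median_delta"])
    y = boxcox_transform(frame["median_delta"], lambda_)
    all_terms = ["kappa", "kappa2", "n", "n2"]
    rows = []
    for k in range(len(all_terms) + 1):
        for terms in combinations(all_terms, k):
            X = _design(frame, terms) if terms else np.ones((len(frame), 1))
            fit = sm.OLS(y, X).fit()
            rows.append({
                "terms": "+".join(terms) if terms else "intercept-only",
                "adj_r2": float(fit.rsquared_adj),
                "n_params": X.shape[1],
            })
    return (
        pd.DataFrame(rows)
        .sort_values("adj_r2", ascending=False)
        .reset_index(drop=True)
    )
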