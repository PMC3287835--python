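"""Trait residualization and distance-from-median quantities.

The quantitative trait is first residualized on age, sex, and smoking by
ordinary least squares over the full cohort; sampling and association analysis
both operate on the residual Y_i.  Distance-dependent designs use
d_i = |Y_i - Y_med| scaled by d_max = max(Y_max - Y_med, Y_med - Y_min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ResidualTrait", "residualize", "median_distance"]

COVARIATE_COLUMNS = ("age", "sex", "smoking")


@dataclass
class ResidualTrait:
    """Residual trait with its median and distance-from-median summary."""

    y: np.ndarray
    y_med: float
    y_min: float
    y_max: float
    d: np.ndarray  # d_i = |Y_i - Y_med| >= 0
    d_max: float  # max(Y_max - Y_med, Y_med - Y_min)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def degenerate(self) -> bool:
        """True when all residuals are equal (probability designs undefined)."""
        return self.d_max == 0.0


def residualize(trait: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of the trait on intercept + age + sex + smoking.

    Computed over the full cohort, before any selection.  Raises
    ``np.linalg.LinAlgError`` if the covariate matrix is rank deficient.
    """
    y = np.asarray(trait, dtype=float)
    X = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    if y.shape[0] != X.shape[0]:
        raise ValueError("trait and covariate table lengths differ")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values are not supported")
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more individuals than regression parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def median_distance(y: np.ndarray) -> ResidualTrait:
    """Distances from the sample median and the maximum distance.

    The median of an even-length vector is the midpoint of the two central
    order statistics.  A constant vector yields ``d_max = 0``; downstream
    probability designs reject that case.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    y_med = float(np.median(y))
    y_min, y_max = float(y.min()), float(y.max())
    d = np.abs(y - y_med)
    d_max = max(y_max - y_med, y_med - y_min)
    return ResidualTrait(y=y, y_med=y_med, y_min=y_min, y_max=y_max,
                         d=d, d_max=d_max)
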