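"""Column autoscaling with explicit fit/apply separation.

Autoscaling (mean-centre, then divide by the column standard deviation,
divisor n-1) is the only pretreatment the classification models use.  Fit and
apply are separate so cross-validation can fit the scaling on training folds
only and never leak held-out statistics.  Columns whose standard deviation is
numerically zero (dead spectral channels, which appear after aggressive
feature elimination) are centred but not divided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingModel", "autoscale_fit", "autoscale_apply", "autoscale_invert"]

#: columns with sd below this are treated as constant and centred only
CONSTANT_SD_THRESHOLD = 1e-12


@dataclass(frozen=True)
class ScalingModel:
    means: np.ndarray
    sds: np.ndarray
    constant: np.ndarray  # boolean mask of centred-only columns

    @property
    def n_variables(self) -> int:
        return self.means.size


def autoscale_fit(X: np.ndarray) -> ScalingModel:
    """Fit per-column means and standard deviations (divisor n-1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least two samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds < CONSTANT_SD_THRESHOLD
    return ScalingModel(means=means, sds=sds, constant=constant)


def _check_columns(m: ScalingModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.n_variables:
        raise ValueError(
            f"matrix has {X.shape[1]} columns but the scaling model was fit on "
            f"{m.n_variables}"
        )
    return X

def autoscale_apply(m: ScalingModel, X: np.ndarray) -> np.ndarray:
    """(X - means) / sds, with constant columns centred only."""
    X = _check_columns(m, X)
    denom = np.where(m.constant, 1.0, m.sds)
    return (X - m.means) / denom


def autoscale_invert(m: ScalingModel, Xs: np.ndarray) -> np.ndarray:
    """Undo :func:`autoscale_apply` (exact for all columns)."""
    Xs = _check_columns(m, Xs)
    denom = np.where(m.constant, 1.0, m.sds)
    return Xs * denom + m.means
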