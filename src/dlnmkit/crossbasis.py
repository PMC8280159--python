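"""Exposure-lag cross-basis construction and single-point basis vectors.

The cross-basis row for a stratum sums, over its lagged exposure history,
the outer product of the exposure basis evaluated at the lagged exposure
value with the lag basis evaluated at the lag.  The lag basis carries no
intercept, and every lag-basis column is additionally anchored to equal 0
at lag 0 (each column is shifted by its value at 0); together these force
the fitted log rate ratio to be exactly 0 at lag 0 for every exposure.

Column ordering is exposure-major: column index ``j * df_lag + k`` pairs
exposure-basis column ``j`` with lag-basis column ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import ExposureHistory
from .errors import ValidationError
from .splines import BasisSpec, natural_spline_basis


@dataclass
class CrossBasis:
    """N x (df_x * df_lag) cross-basis matrix with its construction metadata."""

    matrix: np.ndarray
    exposure_spec: BasisSpec
    lag_spec: BasisSpec
    lag_max: int

    @property
    def n_columns(self) -> int:
        return self.exposure_spec.n_columns * self.lag_spec.n_columns

    def column_names(self) -> list[str]:
        dx, dl = self.exposure_spec.n_columns, self.lag_spec.n_columns
        return [f"cb_x{j}_l{k}" for j in range(dx) for k in range(dl)]


def lag_basis_anchored(lags, lag_spec: BasisSpec) -> np.ndarray:
    """Lag basis evaluated at ``lags`` with each column shifted to be 0 at
    lag 0 (the constraint mechanism fixing the rate ratio to 1 at lag 0)."""
    if lag_spec.intercept:
        raise ValidationError("lag basis must exclude the intercept")
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    b = natural_spline_basis(lags, lag_spec)
    b0 = natural_spline_basis(np.array([0.0]), lag_spec)
    return b - b0


def build_cross_basis(histories: Sequence[ExposureHistory],
                      exposure_spec: BasisSpec,
                      lag_spec: BasisSpec) -> CrossBasis:
    """Build the cross-basis matrix from aligned exposure histories."""
    if not histories:
        raise ValidationError("no exposure histories supplied")
    lag_max = histories[0].lag_max
    for i, h in enumerate(histories):
        if h.lag_max != lag_max:
            raise ValidationError(
                f"history {i} has lag_max={h.lag_max}, expected {lag_max}")
    X = np.stack([h.values for h in histories])          # (n, L+1)
    n = X.shape[0]
    lags = np.arange(lag_max + 1, dtype=float)
    Bl = lag_basis_anchored(lags, lag_spec)              # (L+1, dl)
    dx, dl = exposure_spec.n_columns, lag_spec.n_columns
    M = np.zeros((n, dx * dl))
    for l in range(lag_max + 1):
        Bx = natural_spline_basis(X[:, l], exposure_spec)   # (n, dx)
        M += (Bx[:, :, None] * Bl[l][None, None, :]).reshape(n, dx * dl)
    return CrossBasis(matrix=M, exposure_spec=exposure_spec,
                      lag_spec=lag_spec, lag_max=lag_max)


def point_basis(x: float, l: float, cb: CrossBasis) -> np.ndarray:
    """Basis vector for a single (exposure, lag) point, flattened in the
    same exposure-major order as the cross-basis columns."""
    if not 0 <= l <= cb.lag_max:
        raise ValidationError(f"lag {l} outside [0, {cb.lag_max}]")
    bx = natural_spline_basis(np.array([float(x)]), cb.exposure_spec)[0]
    bl = lag_basis_anchored(np.array([float(l)]), cb.lag_spec)[0]
    return np.outer(bx, bl).ravel()


def point_basis_grid(xs, ls, cb: CrossBasis) -> np.ndarray:
    """Point bases for a full (exposure, lag) grid.

    Returns an array of shape ``(len(xs), len(ls), df_x * df_lag)``.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ls = np.atleast_1d(np.asarray(ls, dtype=float))
    if ls.min() < 0 or ls.max() > cb.lag_max:
        raise ValidationError(f"lag grid outside [0, {cb.lag_max}]")
    Bx = natural_spline_basis(xs, cb.exposure_spec)      # (nx, dx)
    Bl = lag_basis_anchored(ls, cb.lag_spec)             # (nl, dl)
    out = Bx[:, None, :, None] * Bl[None, :, None, :]
    nx, nl = len(xs), len(ls)
    return out.reshape(nx, nl, cb.n_columns)
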