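"""Backward-perspective rate-ratio prediction over the exposure-lag surface.

Effects are incidence rate ratios (IRR) relative to a reference exposure
level: for a grid point (x, l) the log IRR is the contrast
``(point_basis(x, l) - point_basis(reference, l))' beta``, with the delta
method applied to the cross-basis block of the chosen covariance for
standard errors.  Cumulative IRRs sum log IRRs over lags 0..horizon
inclusive (lag 0 contributes exactly 0 under the lag-0 constraint), with
the variance of the summed contrast vector — not the sum of variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cluster import RobustVcov
from .crossbasis import CrossBasis, point_basis_grid
from .errors import ValidationError
from .negbin import NBFit

DEFAULT_EXPOSURE_GRID = np.arange(1.0, 82.0)
DEFAULT_LAG_GRID = np.arange(0, 31)


@dataclass
class EffectSurface:
    """Predicted IRR and cumulative IRR over an (exposure, lag) grid."""

    exposure_grid: np.ndarray
    lag_grid: np.ndarray
    reference: float
    level: float
    log_irr: np.ndarray           # (nx, nl)
    se: np.ndarray
    cum_log_irr: np.ndarray
    cum_se: np.ndarray
    contrasts: np.ndarray = field(repr=False)       # (nx, nl, q)
    cum_contrasts: np.ndarray = field(repr=False)
    vcov_block: np.ndarray = field(repr=False)      # (q, q)

    @property
    def _z(self) -> float:
        return float(norm.ppf(0.5 + self.level / 2))

    @property
    def irr(self) -> np.ndarray:
        return np.exp(self.log_irr)

    @property
    def irr_low(self) -> np.ndarray:
        return np.exp(self.log_irr - self._z * self.se)

    @property
    def irr_high(self) -> np.ndarray:
        return np.exp(self.log_irr + self._z * self.se)

    @property
    def irr_cum(self) -> np.ndarray:
        return np.exp(self.cum_log_irr)

    @property
    def irr_cum_low(self) -> np.ndarray:
        return np.exp(self.cum_log_irr - self._z * self.cum_se)

    @property
    def irr_cum_high(self) -> np.ndarray:
        return np.exp(self.cum_log_irr + self._z * self.cum_se)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format table, one row per (exposure, lag) cell."""
        nx, nl = self.log_irr.shape
        xg, lg = np.meshgrid(self.exposure_grid, self.lag_grid, indexing="ij")
        return pd.DataFrame({
            "exposure": xg.ravel(), "lag": lg.ravel(),
            "log_irr": self.log_irr.ravel(), "se": self.se.ravel(),
            "irr": self.irr.ravel(),
            "irr_low": self.irr_low.ravel(),
            "irr_high": self.irr_high.ravel(),
            "irr_cum": self.irr_cum.ravel(),
            "irr_cum_low": self.irr_cum_low.ravel(),
            "irr_cum_high": self.irr_cum_high.ravel(),
        })

    def _x_index(self, x: float) -> int:
        idx = np.flatnonzero(np.isclose(self.exposure_grid, x))
        if idx.size == 0:
            raise ValidationError(f"exposure {x} not on the surface grid")
        return int(idx[0])

    def _l_index(self, l: float) -> int:
        idx = np.flatnonzero(np.isclose(self.lag_grid, l))
        if idx.size == 0:
            raise ValidationError(f"lag {l} not on the surface grid")
        return int(idx[0])


def _beta_block(fit: NBFit, vcov) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([i for i, c in enumerate(fit.column_names)
                    if c.startswith("cb_")])
    if idx.size == 0:
        raise ValidationError("fit has no cross-basis columns")
    V = vcov.matrix if isinstance(vcov, RobustVcov) else np.asarray(vcov)
    if V.shape[0] == len(fit.column_names):
        V = V[np.ix_(idx, idx)]
    elif V.shape[0] != idx.size:
        raise ValidationError("covariance dimension mismatch")
    return fit.coefficients[idx], V


def predict_surface(fit: NBFit, vcov, cb: CrossBasis,
                    exposure_grid=None, lag_grid=None,
                    reference: float = 50.0,
                    level: float = 0.95) -> EffectSurface:
    """Predict the IRR surface centred at ``reference`` exposure.

    ``vcov`` is a :class:`RobustVcov` or a raw covariance matrix (full
    coefficient order or the cross-basis block alone).
    """
    exposure_grid = (DEFAULT_EXPOSURE_GRID if exposure_grid is None
                     else np.atleast_1d(np.asarray(exposure_grid, float)))
    lag_grid = (DEFAULT_LAG_GRID if lag_grid is None
                else np.atleast_1d(np.asarray(lag_grid, float)))
    lo, hi = cb.exposure_spec.boundary_knots
    if not lo <= reference <= hi:
        warnings.warn(
            f"reference {reference} outside exposure boundary knots "
            f"[{lo}, {hi}]; prediction uses the linear tails", stacklevel=2)
    beta, V = _beta_block(fit, vcov)

    pb = point_basis_grid(exposure_grid, lag_grid, cb)       # (nx, nl, q)
    pb_ref = point_basis_grid([reference], lag_grid, cb)[0]  # (nl, q)
    contrasts = pb - pb_ref[None, :, :]
    log_irr = contrasts @ beta
    se = np.sqrt(np.maximum(np.einsum("xlq,qr,xlr->xl",
                                      contrasts, V, contrasts), 0.0))
    cum_contrasts = np.cumsum(contrasts, axis=1)
    cum_log_irr = np.cumsum(log_irr, axis=1)
    cum_se = np.sqrt(np.maximum(np.einsum("xlq,qr,xlr->xl",
                                          cum_contrasts, V, cum_contrasts),
                                0.0))
    return EffectSurface(
        exposure_grid=exposure_grid, lag_grid=lag_grid,
        reference=float(reference), level=level,
        log_irr=log_irr, se=se, cum_log_irr=cum_log_irr, cum_se=cum_se,
        contrasts=contrasts, cum_contrasts=cum_contrasts, vcov_block=V)


def cumulative_irr(surface: EffectSurface, x: float, horizon: int
                   ) -> tuple[float, tuple[float, float]]:
    """Cumulative IRR at exposure ``x`` through lag ``horizon`` inclusive,
    with its delta-method confidence interval."""
    i, j = surface._x_index(x), surface._l_index(horizon)
    z = surface._z
    est = surface.cum_log_irr[i, j]
    se = surface.cum_se[i, j]
    return float(np.exp(est)), (float(np.exp(est - z * se)),
                                float(np.exp(est + z * se)))


def scenario_irr_cum(fit: NBFit, vcov, cb: CrossBasis, reference: float,
                     new_prevalence, horizon: int,
                     level: float = 0.95) -> pd.DataFrame:
    """What-if scenario: cumulative IRR of switching from the reference
    prevalence to a new prevalence path sustained into the future.

    ``new_prevalence`` is a scalar (constant path) or a sequence of
    ``horizon + 1`` per-year values for years 0..horizon after the change.
    At year ``h`` the exposure experienced at lag ``l <= h`` is the path
    value for year ``h - l``; lags before the change sit at the reference
    and contribute nothing.  Returns one row per year 0..horizon.
    """
    if not 0 <= horizon <= cb.lag_max:
        raise ValidationError(f"horizon {horizon} outside [0, {cb.lag_max}]")
    path = np.atleast_1d(np.asarray(new_prevalence, dtype=float))
    if path.size == 1:
        path = np.full(horizon + 1, path[0])
    elif path.size > horizon + 1:
        raise ValidationError(
            f"prevalence path length {path.size} exceeds horizon+1 = "
            f"{horizon + 1}")
    elif path.size != horizon + 1:
        raise ValidationError(
            f"prevalence path must be scalar or length {horizon + 1}, "
            f"got {path.size}")
    if path.min() < 0 or path.max() > 100:
        raise ValidationError("prevalence path values must lie in [0, 100]")

    beta, V = _beta_block(fit, vcov)
    z = float(norm.ppf(0.5 + level / 2))
    lags = np.arange(horizon + 1, dtype=float)
    pb_ref = point_basis_grid([reference], lags, cb)[0]      # (h+1, q)

    rows = []
    for h in range(horizon + 1):
        w = np.zeros(cb.n_columns)
        for l in range(h + 1):
            pb_new = point_basis_grid([path[h - l]], [float(l)], cb)[0, 0]
            w += pb_new - pb_ref[l]
        est = float(w @ beta)
        se = float(np.sqrt(max(w @ V @ w, 0.0)))
        rows.append({"year": h, "irr_cum": np.exp(est),
                     "irr_cum_low": np.exp(est - z * se),
                     "irr_cum_high": np.exp(est + z * se)})
    return pd.DataFrame(rows)
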