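"""Negative-binomial (NB2) GLM with log link, offset and cross-basis terms.

The linear predictor is: intercept + cross-basis block + country dummies +
age-group dummies + male indicator + outcome-year dummies + age x gender
interaction, with log population at risk as the offset.  Estimation is full
maximum likelihood, alternating IRLS for the coefficients given the
dispersion with univariate ML for the dispersion given the coefficients.

The dispersion follows the NB2 convention: Var(Y) = mu + mu^2 / theta.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .crossbasis import CrossBasis
from .data import StrataRecord
from .errors import ComparisonError, RankDeficiencyError, ValidationError

logger = logging.getLogger(__name__)

_THETA_MIN, _THETA_MAX = 1e-3, 1e8


@dataclass
class DesignMatrix:
    """Fully dummy-coded design with response, offset and row metadata."""

    X: np.ndarray
    column_names: list[str]
    y: np.ndarray
    offset: np.ndarray
    row_ids: list[str]
    registry: list[str]
    reference_levels: dict[str, str]

    def __post_init__(self) -> None:
        n, p = self.X.shape
        if len(self.y) != n or len(self.offset) != n:
            raise ValidationError("response/offset not aligned with design")
        if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
            raise ValidationError("response must be non-negative integers")
        if not np.all(np.isfinite(self.offset)):
            raise ValidationError("offset must be finite")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def fingerprint(self) -> str:
        """Hash of (response, offset) identifying the data being fitted."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.y, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.offset, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]

    def cb_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.column_names)
                         if c.startswith("cb_")])


@dataclass
class NBFit:
    coefficients: np.ndarray
    theta: float
    model_vcov: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    column_names: list[str]
    data_fingerprint: str
    label: str = "model"

    @property
    def n_params(self) -> int:
        """Total parameter count including the dispersion."""
        return len(self.coefficients) + 1


def build_design(records: Sequence[StrataRecord], cb: CrossBasis,
                 interaction: bool = True) -> DesignMatrix:
    """Assemble the design matrix from records and an aligned cross-basis.

    Dummy coding uses the first level in sorted order as the reference for
    each categorical; the gender indicator is 1 for male.  Factors with a
    single observed level contribute no columns.
    """
    if len(records) != cb.matrix.shape[0]:
        raise ValidationError(
            f"{len(records)} records vs {cb.matrix.shape[0]} cross-basis rows")
    df = pd.DataFrame({
        "country": [r.country for r in records],
        "age_group": [r.age_group for r in records],
        "gender": [r.gender for r in records],
        "outcome_year": [str(r.outcome_year) for r in records],
    })
    cols: list[np.ndarray] = [np.ones(len(records))]
    names: list[str] = ["intercept"]
    cols.append(cb.matrix)
    names.extend(cb.column_names())

    refs: dict[str, str] = {}
    male = (df["gender"] == "M").to_numpy(dtype=float)

    def add_dummies(var: str, prefix: str) -> np.ndarray | None:
        levels = sorted(df[var].unique())
        refs[var] = levels[0]
        if len(levels) == 1:
            return None
        block = np.column_stack([
            (df[var] == lev).to_numpy(dtype=float) for lev in levels[1:]])
        cols.append(block)
        names.extend(f"{prefix}[{lev}]" for lev in levels[1:])
        return block

    add_dummies("country", "country")
    age_block = add_dummies("age_group", "age")
    refs["gender"] = "F"
    if df["gender"].nunique() > 1:
        cols.append(male[:, None])
        names.append("gender[M]")
    add_dummies("outcome_year", "year")
    if interaction and age_block is not None and df["gender"].nunique() > 1:
        inter = age_block * male[:, None]
        cols.append(inter)
        age_levels = sorted(df["age_group"].unique())[1:]
        names.extend(f"age[{lev}]:gender[M]" for lev in age_levels)

    X = np.column_stack(cols)
    _check_rank(X, names)
    dm = DesignMatrix(
        X=X, column_names=names,
        y=np.array([r.cases for r in records], dtype=float),
        offset=np.log(np.array([r.population for r in records])),
        row_ids=[r.stratum_id for r in records],
        registry=[r.registry for r in records],
        reference_levels=refs,
    )
    logger.info("design: %d rows x %d columns (references: %s)",
                dm.n_obs, dm.n_params, refs)
    return dm


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(X / scale, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-9 * diag.max()
    if bad.any():
        aliased = [names[i] for i in np.flatnonzero(bad)]
        raise RankDeficiencyError(f"aliased design columns: {aliased}")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))))


def _irls(X: np.ndarray, y: np.ndarray, offset: np.ndarray, beta: np.ndarray,
          theta: float | None, tol: float = 1e-10, max_iter: int = 50
          ) -> tuple[np.ndarray, bool]:
    """IRLS for the log-link GLM; ``theta=None`` fits the Poisson limit."""
    eta = X @ beta + offset
    for _ in range(max_iter):
        mu = np.exp(eta)
        if not np.all(np.isfinite(mu)) or mu.max() > 1e290:
            raise FloatingPointError(
                "linear predictor overflow during IRLS (possible separation)")
        w = mu if theta is None else mu * theta / (theta + mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        eta_new = X @ beta_new + offset
        done = np.max(np.abs(beta_new - beta)) < tol * (
            1 + np.max(np.abs(beta)))
        beta, eta = beta_new, eta_new
        if done:
            return beta, True
    return beta, False


def fit_negbin(design: DesignMatrix, init: np.ndarray | None = None,
               tol: float = 1e-8, max_iter: int = 50,
               theta: float | None = None, label: str = "model") -> NBFit:
    """Fit the NB2 GLM by full maximum likelihood.

    Alternates IRLS for the coefficients at fixed dispersion with a
    univariate (Brent, on log theta) ML step for the dispersion, until the
    relative log-likelihood change falls below ``tol``.  Passing ``theta``
    fixes the dispersion instead of estimating it.

    Non-convergence is reported via ``converged=False``, not an exception;
    numerical overflow (separation) raises ``FloatingPointError``.
    """
    X, y, offset = design.X, design.y, design.offset
    fixed_theta = theta is not None

    if init is not None:
        beta = np.asarray(init, dtype=float)
    else:
        beta = np.zeros(design.n_params)
        beta[design.column_names.index("intercept")] = np.log(
            np.mean(y) / np.mean(np.exp(offset)) + 1e-12)
        beta, _ = _irls(X, y, offset, beta, theta=None)   # Poisson init

    if not fixed_theta:
        mu = np.exp(X @ beta + offset)
        theta = _theta_ml(y, mu)
    ll = _nb_loglik(y, np.exp(X @ beta + offset), theta)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta, _ = _irls(X, y, offset, beta, theta=theta)
        mu = np.exp(X @ beta + offset)
        if not fixed_theta:
            theta = _theta_ml(y, mu)
        ll_new = _nb_loglik(y, mu, theta)
        if abs(ll_new - ll) < tol * (abs(ll) + 1e-8):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("%s: no convergence in %d outer iterations", label,
                       max_iter)

    mu = np.exp(X @ beta + offset)
    # observed information for beta at theta-hat
    w_obs = theta * mu * (theta + y) / (theta + mu) ** 2
    H = X.T @ (X * w_obs[:, None])
    vcov = np.linalg.inv(H)
    vcov = 0.5 * (vcov + vcov.T)

    n_par = design.n_params + (0 if fixed_theta else 1)
    aic = -2.0 * ll + 2.0 * n_par
    return NBFit(coefficients=beta, theta=float(theta), model_vcov=vcov,
                 loglik=ll, aic=aic, converged=converged, n_iter=it,
                 column_names=list(design.column_names),
                 data_fingerprint=design.fingerprint(), label=label)


def _theta_ml(y: np.ndarray, mu: np.ndarray) -> float:
    """ML dispersion at fixed mean, maximized over log theta."""
    def nll(log_t: float) -> float:
        return -_nb_loglik(y, mu, np.exp(log_t))

    res = minimize_scalar(nll, bounds=(np.log(_THETA_MIN), np.log(_THETA_MAX)),
                          method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


def score_vectors(fit: NBFit, design: DesignMatrix) -> np.ndarray:
    """Per-observation score contributions for the coefficient vector,
    evaluated at (beta-hat, theta-hat) with the dispersion held fixed."""
    mu = np.exp(design.X @ fit.coefficients + design.offset)
    u = (design.y - mu) * fit.theta / (fit.theta + mu)
    return design.X * u[:, None]


def compare_aic(fits: Sequence[NBFit]) -> pd.DataFrame:
    """Rank fits by AIC (ascending) with deltas to the best model.

    All fits must have been obtained on the same response and offset.
    """
    if len(fits) < 2:
        raise ComparisonError("need at least two fits to compare")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ComparisonError(
            "fits were not obtained on the same data (fingerprints differ)")
    rows = [{"label": f.label, "aic": f.aic, "loglik": f.loglik,
             "n_params": f.n_params, "converged": f.converged} for f in fits]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable")
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out.reset_index(drop=True)


def fit_candidate_set(records: Sequence[StrataRecord], histories,
                      exposure_df: int = 4, lag_df: int = 3,
                      full_cb: CrossBasis | None = None,
                      **fit_kwargs) -> list[NBFit]:
    """The pre-specified four-model comparison set.

    Candidates: the full model (df 4/4 cross-basis, age x gender
    interaction); the same without the interaction; df 3/3 splines with the
    interaction; df 3/3 without the interaction.
    """
    from .crossbasis import build_cross_basis
    from .splines import default_knots

    exposures = np.concatenate([h.values for h in histories])
    lags = np.arange(histories[0].lag_max + 1, dtype=float)
    if full_cb is None:
        full_cb = build_cross_basis(
            histories,
            default_knots(exposures, df=4),
            default_knots(lags, df=4, scale="log-lag"))
    reduced_cb = build_cross_basis(
        histories,
        default_knots(exposures, df=3),
        default_knots(lags, df=3, scale="log-lag"))
    fits = []
    for label, cb, inter in [
            ("full_df4_interaction", full_cb, True),
            ("df4_no_interaction", full_cb, False),
            ("df3_interaction", reduced_cb, True),
            ("df3_no_interaction", reduced_cb, False)]:
        dm = build_design(records, cb, interaction=inter)
        fits.append(fit_negbin(dm, label=label, **fit_kwargs))
    return fits
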