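"""Simulation-based scaled (quantile) residuals for the fitted count model.

For each stratum, draws from the fitted negative-binomial predictive
distribution are compared with the observed count; the residual is the
randomized probability-integral-transform position of the observation among
the draws, uniform on [0, 1] when the model is correct.  Per-stratum RNG
substreams are keyed by (seed, stratum id), so residuals do not depend on
row order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .negbin import DesignMatrix, NBFit


@dataclass
class ScaledResiduals:
    values: np.ndarray
    n_sim: int
    seed: int


def _stratum_stream(seed: int, stratum_id: str) -> np.random.Generator:
    digest = hashlib.sha256(stratum_id.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_scaled_residuals(fit: NBFit, design: DesignMatrix,
                              n_sim: int = 250, seed: int = 0
                              ) -> ScaledResiduals:
    """Randomized PIT residuals from ``n_sim`` NB draws per stratum."""
    if not fit.converged:
        raise ValidationError("cannot compute residuals for a non-converged fit")
    if n_sim < 100:
        raise ValidationError(f"n_sim must be >= 100, got {n_sim}")
    mu = np.exp(design.X @ fit.coefficients + design.offset)
    p_nb = fit.theta / (fit.theta + mu)
    y = design.y
    out = np.empty(design.n_obs)
    for i, sid in enumerate(design.row_ids):
        rng = _stratum_stream(seed, sid)
        sims = rng.negative_binomial(fit.theta, p_nb[i], size=n_sim)
        n_below = int(np.sum(sims < y[i]))
        n_tied = int(np.sum(sims == y[i]))
        # randomized PIT: uniform within the tie band, strictly inside (0,1)
        out[i] = (n_below + rng.uniform() * (n_tied + 1)) / (n_sim + 1)
    return ScaledResiduals(values=out, n_sim=n_sim, seed=seed)


def residual_plot_data(res: ScaledResiduals) -> pd.DataFrame:
    """QQ table: sorted residuals against uniform plotting positions."""
    obs = np.sort(np.asarray(res.values, dtype=float))
    n = len(obs)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"expected": expected, "observed": obs})
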