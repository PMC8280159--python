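"""YAML serialization of a fitted model bundle.

A bundle holds everything needed to reproduce downstream predictions
without refitting: coefficients, dispersion, both covariances, the basis
specs, lag range, column order and reference levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .cluster import RobustVcov
from .crossbasis import CrossBasis
from .negbin import NBFit
from .splines import BasisSpec


@dataclass
class FitBundle:
    fit: NBFit
    cb: CrossBasis
    robust: RobustVcov | None = None

    @property
    def default_vcov(self):
        """Robust covariance when available, else the model-based one."""
        return self.robust if self.robust is not None else self.fit.model_vcov


def save_fit_bundle(path, bundle: FitBundle) -> None:
    fit, cb = bundle.fit, bundle.cb
    doc = {
        "model": {
            "label": fit.label,
            "coefficients": {c: float(v) for c, v in
                             zip(fit.column_names, fit.coefficients)},
            "theta": fit.theta,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "data_fingerprint": fit.data_fingerprint,
            "model_vcov": fit.model_vcov.tolist(),
        },
        "cross_basis": {
            "exposure_spec": cb.exposure_spec.to_dict(),
            "lag_spec": cb.lag_spec.to_dict(),
            "lag_max": cb.lag_max,
            "column_order": "exposure-major (exposure index varies slowest)",
        },
    }
    if bundle.robust is not None:
        doc["robust_vcov"] = {
            "matrix": bundle.robust.matrix.tolist(),
            "n_clusters": bundle.robust.n_clusters,
            "correction": bundle.robust.correction,
            "default_for_intervals": True,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_fit_bundle(path) -> FitBundle:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    m = doc["model"]
    names = list(m["coefficients"].keys())
    fit = NBFit(
        coefficients=np.array(list(m["coefficients"].values()), dtype=float),
        theta=float(m["theta"]),
        model_vcov=np.array(m["model_vcov"], dtype=float),
        loglik=float(m["loglik"]), aic=float(m["aic"]),
        converged=bool(m["converged"]), n_iter=int(m["n_iter"]),
        column_names=names, data_fingerprint=str(m["data_fingerprint"]),
        label=str(m.get("label", "model")))
    cbd = doc["cross_basis"]
    cb = CrossBasis(
        matrix=np.zeros((0, 0)),
        exposure_spec=BasisSpec.from_dict(cbd["exposure_spec"]),
        lag_spec=BasisSpec.from_dict(cbd["lag_spec"]),
        lag_max=int(cbd["lag_max"]))
    robust = None
    if "robust_vcov" in doc:
        r = doc["robust_vcov"]
        robust = RobustVcov(matrix=np.array(r["matrix"], dtype=float),
                            n_clusters=int(r["n_clusters"]),
                            correction=str(r["correction"]))
    return FitBundle(fit=fit, cb=cb, robust=robust)
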