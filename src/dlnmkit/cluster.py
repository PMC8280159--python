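"""Cluster-robust sandwich covariance with registry as the cluster variable.

bread * meat * bread, where the bread is the model-based covariance and the
meat sums outer products of cluster-summed scores; a CR1-type G/(G-1)
finite-sample factor is applied.  Scores are evaluated at the fitted
coefficients with the dispersion held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .negbin import DesignMatrix, NBFit, score_vectors


@dataclass
class RobustVcov:
    matrix: np.ndarray
    n_clusters: int
    correction: str = "CR1 G/(G-1)"


def cluster_sandwich(fit: NBFit, design: DesignMatrix,
                     cluster_ids: Sequence[str] | None = None) -> RobustVcov:
    """Cluster-robust covariance of the coefficient vector.

    ``cluster_ids`` defaults to the registry labels carried by the design.
    """
    if cluster_ids is None:
        cluster_ids = design.registry
    cluster_ids = list(cluster_ids)
    if len(cluster_ids) != design.n_obs:
        raise ValidationError("cluster_ids not aligned with design rows")
    if any(c is None or (isinstance(c, str) and not c.strip())
           for c in cluster_ids):
        raise ValidationError("empty cluster labels")
    labels, inverse = np.unique(np.asarray(cluster_ids, dtype=object),
                                return_inverse=True)
    G = len(labels)
    if G < 2:
        raise ValidationError(
            f"cluster sandwich requires >= 2 clusters, got {G}")

    scores = score_vectors(fit, design)                  # (n, p)
    p = scores.shape[1]
    cluster_scores = np.zeros((G, p))
    np.add.at(cluster_scores, inverse, scores)
    meat = cluster_scores.T @ cluster_scores
    bread = fit.model_vcov
    V = bread @ meat @ bread * (G / (G - 1))
    V = 0.5 * (V + V.T)
    return RobustVcov(matrix=V, n_clusters=G)
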