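"""Restricted cubic (natural) spline bases.

A natural cubic spline with ``k`` knots is piecewise cubic, twice
continuously differentiable, and constrained to be linear beyond the two
boundary knots; besides the intercept it contributes ``k - 1`` free
parameters.  The basis here is built from a cubic B-spline design matrix
with the two second-derivative boundary constraints projected out (the
standard construction), so equivalence with other natural-spline
parameterizations holds up to an invertible linear recombination of
columns — that equivalence, not bit-identity, is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DegenerateRangeError, ValidationError

SCALES = ("identity", "log-lag")


@dataclass(frozen=True)
class BasisSpec:
    """Configuration of one natural-spline basis.

    ``df`` is the number of basis columns (excluding the optional
    intercept); with ``df`` columns the spec carries ``df - 1`` interior
    knots and two boundary knots, i.e. ``df + 1`` knots in total.
    """

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False
    scale: str = "identity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "interior_knots",
                           tuple(float(k) for k in self.interior_knots))
        object.__setattr__(self, "boundary_knots",
                           (float(self.boundary_knots[0]),
                            float(self.boundary_knots[1])))
        if self.df < 1:
            raise ValidationError(f"df must be >= 1, got {self.df}")
        if len(self.interior_knots) != self.df - 1:
            raise ValidationError(
                f"df={self.df} requires {self.df - 1} interior knots, "
                f"got {len(self.interior_knots)}")
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValidationError("boundary knots must satisfy lo < hi")
        if any(not lo < k < hi for k in self.interior_knots):
            raise ValidationError(
                "interior knots must lie strictly between boundary knots")
        if list(self.interior_knots) != sorted(set(self.interior_knots)):
            raise ValidationError("interior knots must be strictly increasing")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")

    @property
    def all_knots(self) -> np.ndarray:
        """All knots, boundary included, in increasing order."""
        return np.r_[self.boundary_knots[0], self.interior_knots,
                     self.boundary_knots[1]]

    @property
    def n_columns(self) -> int:
        return self.df + (1 if self.intercept else 0)

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
            "intercept": self.intercept,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(df=int(d["df"]),
                   interior_knots=tuple(d["interior_knots"]),
                   boundary_knots=tuple(d["boundary_knots"]),
                   intercept=bool(d.get("intercept", False)),
                   scale=str(d.get("scale", "identity")))


def default_knots(values, df: int, scale: str = "identity",
                  intercept: bool = False) -> BasisSpec:
    """Boundary knots at observed min/max, with df - 1 interior knots.

    On the identity scale interior knots sit at equally spaced quantiles
    of the observed values.  On the ``log-lag`` scale they sit at equally
    spaced positions in log(value + 1) between the boundaries (sample
    quantiles are invariant under monotone transforms, so quantile
    placement on a transformed scale would be a no-op); this concentrates
    flexibility at short lags.
    """
    values = np.asarray(values, dtype=float)
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    vmin, vmax = float(values.min()), float(values.max())
    if not vmin < vmax:
        raise DegenerateRangeError(
            f"cannot place knots on constant values (all = {vmin})")
    if df == 1:
        interior: tuple[float, ...] = ()
    else:
        probs = np.arange(1, df) / df
        if scale == "log-lag":
            grid = np.log1p(vmin) + probs * (np.log1p(vmax) - np.log1p(vmin))
            interior = tuple(np.expm1(grid))
        else:
            interior = tuple(np.quantile(values, probs))
        if len(set(interior)) != len(interior):
            raise DegenerateRangeError(
                f"tied quantile knots {interior}; too few distinct values "
                f"for df={df}")
    return BasisSpec(df=df, interior_knots=interior,
                     boundary_knots=(vmin, vmax), intercept=intercept,
                     scale=scale)


def _bspline_design(aug_knots: np.ndarray, x: np.ndarray, deriv: int = 0
                    ) -> np.ndarray:
    """Cubic B-spline design matrix (or derivative) at points inside the
    boundary; columns are the full set of B-spline basis functions."""
    n_basis = len(aug_knots) - 4
    if deriv == 0:
        return BSpline.design_matrix(x, aug_knots, 3,
                                     extrapolate=False).toarray()
    out = np.empty((len(x), n_basis))
    eye = np.eye(n_basis)
    for j in range(n_basis):
        out[:, j] = BSpline(aug_knots, eye[j], 3).derivative(deriv)(x)
    return out


def natural_spline_basis(x, spec: BasisSpec) -> np.ndarray:
    """Evaluate the natural-spline basis at ``x``.

    Returns an array of shape ``(len(x), spec.n_columns)``.  Points beyond
    the boundary knots are extrapolated linearly (exact, since the basis is
    linear in the tails).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = spec.boundary_knots
    aug = np.r_[[lo] * 4, spec.interior_knots, [hi] * 4]
    n_basis = len(spec.interior_knots) + 4

    xc = np.clip(x, lo, hi)
    basis = _bspline_design(aug, xc)
    # linear extension beyond the boundaries: f(x) = f(b) + (x - b) f'(b)
    below, above = x < lo, x > hi
    if below.any():
        d = _bspline_design(aug, np.array([lo]), deriv=1)
        basis[below] += np.outer(x[below] - lo, d[0])
    if above.any():
        d = _bspline_design(aug, np.array([hi]), deriv=1)
        basis[above] += np.outer(x[above] - hi, d[0])

    # second-derivative-at-boundary constraints define the natural subspace
    const = _bspline_design(aug, np.array([lo, hi]), deriv=2)
    if not spec.intercept:
        basis = basis[:, 1:]
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    out = basis @ q[:, 2:]
    assert out.shape[1] == spec.n_columns
    return out
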