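"""Restricted (natural) cubic spline design matrices for age.

The trajectory model represents the mean MMSE score as a restricted cubic
spline in age: piecewise cubic between k knots, constrained to be linear
beyond the boundary knots, with continuous value, first and second
derivatives everywhere. With knots t_1 < ... < t_k and (x − t)_+ =
max(x − t, 0), the k − 2 nonlinear basis terms are

    c_j(x) = [ (x − t_j)_+³
               − (x − t_{k−1})_+³ (t_k − t_j)/(t_k − t_{k−1})
               + (x − t_k)_+³   (t_{k−1} − t_j)/(t_k − t_{k−1}) ] / (t_k − t_1)²

for j = 1..k−2, and the design row is [1, x, c_1(x), ..., c_{k−2}(x)].
Division by (t_k − t_1)² keeps the cubic columns on a numeric scale
comparable to the linear column.

Knots default to Harrell's sample-quantile convention (k = 5 at the
0.05/0.275/0.5/0.725/0.95 quantiles), computed with linear interpolation
between order statistics (numpy's default, "type 7").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Harrell's recommended knot quantiles by knot count.
KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations defining a restricted cubic spline basis in age."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 3:
            raise ValueError(f"need ≥ 3 knots, got {len(self.knots)}")
        if not all(a < b for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")

    @property
    def k(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        """Nonconstant columns: 1 linear + (k − 2) restricted-cubic terms."""
        return self.k - 1

    @property
    def n_columns(self) -> int:
        """Total design columns including the intercept."""
        return self.k

    def to_dict(self) -> dict:
        return {"knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(tuple(float(t) for t in d["knots"]))


def place_knots(ages, n_knots: int = 5) -> SplineSpec:
    """Place knots at Harrell's empirical quantiles of the observed ages."""
    if n_knots not in KNOT_QUANTILES:
        raise ValueError(
            f"n_knots must be in {sorted(KNOT_QUANTILES)}, got {n_knots}"
        )
    ages = np.asarray(ages, dtype=float).ravel()
    if ages.size < n_knots:
        raise ValueError(f"need at least {n_knots} ages to place {n_knots} knots")
    knots = np.quantile(ages, KNOT_QUANTILES[n_knots])  # linear ("type 7") rule
    if np.unique(knots).size != knots.size:
        raise ValueError(
            "degenerate age distribution: duplicate knots; use fewer knots"
        )
    return SplineSpec(tuple(float(t) for t in knots))


def rcs_design(ages, spec: SplineSpec) -> np.ndarray:
    """Design matrix with rows [1, age, c_1(age), ..., c_{k−2}(age)]."""
    x = np.atleast_1d(np.asarray(ages, dtype=float))
    t = np.asarray(spec.knots)
    k = spec.k
    scale = (t[-1] - t[0]) ** 2
    denom = t[-1] - t[-2]

    def cube_plus(v: np.ndarray) -> np.ndarray:
        return np.maximum(v, 0.0) ** 3

    cols = [np.ones_like(x), x]
    for j in range(k - 2):
        c = (
            cube_plus(x - t[j])
            - cube_plus(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube_plus(x - t[-1]) * (t[-2] - t[j]) / denom
        ) / scale
        cols.append(c)
    return np.column_stack(cols)
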