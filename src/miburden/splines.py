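"""Natural cubic spline basis for age and follow-up-time effects.

The basis is the standard natural (restricted) cubic spline construction:
cubic between the boundary knots and linear beyond them, which makes tail
extrapolation (e.g. predicting at single-year ages outside the observed
5-year band midpoints) well behaved.  A fitted basis stores its knots so the
training design matrix can be reproduced exactly and new points evaluated
consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecificationError

__all__ = ["NaturalSplineBasis"]


@dataclass(frozen=True)
class NaturalSplineBasis:
    """Natural cubic spline basis defined by its knot sequence.

    With ``K`` knots (two boundary, ``K - 2`` interior) the basis has
    ``df = K - 1`` columns and no intercept column: the identity function
    plus ``K - 2`` restricted cubic terms.  ``df >= 2`` is required so at
    least one curvature term accompanies the linear term.

    Parameters
    ----------
    knots
        Strictly increasing knot locations; first and last are the boundary
        knots.
    """

    knots: tuple[float, ...] = field(default=())

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    @classmethod
    def from_data(
        cls,
        x: np.ndarray,
        df: int,
        weights: np.ndarray | None = None,
        boundary: tuple[float, float] | None = None,
    ) -> "NaturalSplineBasis":
        """Place ``df + 1`` knots at (weighted) quantiles of ``x``.

        Boundary knots default to the min/max of ``x``; interior knots sit at
        equally spaced weighted quantiles between them.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise SpecificationError("spline abscissa contains non-finite values")
        if df < 2:
            raise SpecificationError(f"spline df must be >= 2, got {df}")
        distinct = np.unique(x)
        if distinct.size <= df:
            raise SpecificationError(
                f"spline df={df} requires more than {df} distinct x values, "
                f"got {distinct.size}"
            )
        lo, hi = boundary if boundary is not None else (distinct[0], distinct[-1])
        n_interior = df - 1
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        if weights is None:
            interior = np.quantile(x, qs)
        else:
            w = np.asarray(weights, dtype=float)
            order = np.argsort(x)
            cw = np.cumsum(w[order])
            cw /= cw[-1]
            interior = np.interp(qs, cw, x[order])
        knots = np.unique(np.concatenate([[lo], np.atleast_1d(interior), [hi]]))
        if knots.size != df + 1:
            raise SpecificationError(
                "could not place distinct spline knots; reduce df "
                f"(wanted {df + 1} knots, found {knots.size})"
            )
        return cls(knots=tuple(float(k) for k in knots))

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at ``x`` -> array of shape ``(len(x), df)``.

        Column 0 is the identity; columns 1.. are the restricted cubic terms
        d_k(x) - d_{K-1}(x) with d_k the scaled truncated cubic differences,
        which are linear beyond the boundary knots by construction.
        """
        if self.df < 1:
            raise SpecificationError("basis has no knots; fit it first")
        x = np.asarray(x, dtype=float)
        ks = np.asarray(self.knots)
        K = ks.size

        def d(k: int) -> np.ndarray:
            num = _pos_cube(x - ks[k]) - _pos_cube(x - ks[K - 1])
            return num / (ks[K - 1] - ks[k])

        cols = [x]
        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {"knots": list(self.knots)}

    @classmethod
    def from_dict(cls, payload: dict) -> "NaturalSplineBasis":
        return cls(knots=tuple(float(k) for k in payload["knots"]))


def _pos_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3
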