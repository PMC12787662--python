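"""Rank-reduced thin-plate regression spline (TPRS) basis on one covariate.

The smooth f(W) of the week number is represented in the low-rank
thin-plate basis: starting from the full thin-plate system with radial
basis eta(r) = r^3 (the 1-D, second-derivative-penalty case) and null
space {1, W}, the wiggly part is projected onto the leading eigenvectors
of the radial-kernel matrix, the thin-plate side constraint is absorbed,
and the resulting columns are centred (sum-to-zero over the observed
weeks) so the smooth is identifiable against the model intercept.

The returned penalty is positive semi-definite and vanishes exactly on
constant and linear functions of the covariate: straight lines are free,
curvature is charged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["TPRSBasis", "tprs_basis"]


class InsufficientSupportError(ValueError):
    """Raised when the covariate has too few distinct values for the basis."""


@dataclass
class TPRSBasis:
    """A fitted thin-plate regression spline basis.

    ``design`` has ``k - 1`` columns: a centred linear column followed by
    ``k - 2`` centred wiggly columns.  ``penalty`` is the matching
    (k-1)x(k-1) curvature penalty, zero in its first row/column so the
    linear part is unpenalized (the double-penalty shrinkage of that null
    space is applied separately by the fitter).
    """

    x: np.ndarray  # training covariate values (knots)
    design: np.ndarray
    penalty: np.ndarray
    _U: np.ndarray  # eigenvectors of the radial kernel, k columns
    _Z: np.ndarray  # constraint null-space basis, (k, k-2)
    _col_means: np.ndarray
    _x_mean: float

    @property
    def n_columns(self) -> int:
        return self.design.shape[1]

    def evaluate(self, x_new: np.ndarray) -> np.ndarray:
        """Evaluate the basis columns at new covariate values, applying the
        training centring so predictions are on the fitted scale."""
        x_new = np.asarray(x_new, dtype=float)
        E_new = _radial(x_new[:, None] - self.x[None, :])
        wiggly = E_new @ self._U @ self._Z
        lin = (x_new - self._x_mean)[:, None]
        out = np.hstack([lin, wiggly - self._col_means[None, :]])
        return out


def _radial(d: np.ndarray) -> np.ndarray:
    return np.abs(d) ** 3


def tprs_basis(weeks: np.ndarray, k: int = 10) -> TPRSBasis:
    """Build the rank-``k`` TPRS basis and penalty on ``weeks``.

    Parameters
    ----------
    weeks
        Observed covariate values (repeats allowed; distinct values are the
        knots).
    k
        Basis dimension before constraint absorption (>= 3).  The usable
        rank is capped at the number of distinct covariate values.
    """
    x_obs = np.asarray(weeks, dtype=float)
    knots = np.unique(x_obs)
    if knots.size < 3:
        raise InsufficientSupportError("need at least 3 distinct covariate values")
    if k < 3:
        raise InsufficientSupportError("k must be >= 3")
    k = min(k, knots.size)

    E = _radial(knots[:, None] - knots[None, :])
    T = np.column_stack([np.ones_like(knots), knots])

    # Leading eigen-space of the radial kernel (largest |eigenvalue|).
    eigval, eigvec = linalg.eigh(E)
    order = np.argsort(-np.abs(eigval))[:k]
    U = eigvec[:, order]
    D = eigval[order]

    # Absorb the thin-plate side constraint T' U delta = 0.
    TtU = T.T @ U  # (2, k)
    _, _, vh = np.linalg.svd(TtU)
    Z = vh[2:].T  # null-space basis, (k, k-2)

    # Wiggly design at the knots and its penalty Z' D Z (PSD on the
    # constrained subspace; symmetrize and clip tiny negative ripple).
    wiggly_knots = U @ (D[:, None] * Z)  # = E U Z
    S = Z.T @ (D[:, None] * Z)
    S = 0.5 * (S + S.T)
    w_eval, w_vec = linalg.eigh(S)
    S = (w_vec * np.clip(w_eval, 0.0, None)) @ w_vec.T

    # Map from knots to observations, then centre.
    pos = np.searchsorted(knots, x_obs)
    wiggly = wiggly_knots[pos]
    col_means = wiggly.mean(axis=0)
    x_mean = float(x_obs.mean())
    lin = (x_obs - x_mean)[:, None]
    design = np.hstack([lin, wiggly - col_means[None, :]])

    penalty = np.zeros((design.shape[1], design.shape[1]))
    penalty[1:, 1:] = S
    return TPRSBasis(
        x=knots,
        design=design,
        penalty=penalty,
        _U=U,
        _Z=Z,
        _col_means=col_means,
        _x_mean=x_mean,
    )
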