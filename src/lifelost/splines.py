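"""Restricted cubic spline bases.

A restricted (natural) cubic spline with knots ``k_1 < ... < k_K`` is cubic
between adjacent knots and constrained to be *linear* beyond the boundary
knots.  The linear tails are what makes these bases suitable for principled
extrapolation when the spline is placed on the log cumulative excess hazard
against log time: beyond the last knot the log cumulative hazard continues
linearly in ``ln t``, i.e. a Weibull-like tail.

The basis used here is the truncated-power parameterisation

    b_1(x) = x
    b_j(x) = (x - k_j)_+^3 - lam_j (x - k_1)_+^3 - (1 - lam_j)(x - k_K)_+^3

for j = 2..K-1, with ``lam_j = (k_K - k_j) / (k_K - k_1)``.  With K = 2 the
basis degenerates to the single linear column ``[x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "rcs_basis", "rcs_deriv", "knots_from_quantiles"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations for a restricted cubic spline on some (transformed) axis.

    Parameters
    ----------
    knots
        Strictly increasing knot locations, at least two.  The number of
        basis columns is ``len(knots) - 1`` (the spline's degrees of freedom).
    """

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 2:
            raise ValueError("a restricted cubic spline needs at least 2 knots")
        if not all(a < b for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def df(self) -> int:
        """Number of basis columns."""
        return len(self.knots) - 1


def _prep(x, spec: SplineSpec):
    x = np.asarray(x, dtype=float)
    k = np.asarray(spec.knots)
    return x, k


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns an array of shape ``x.shape + (K-1,)``; the first column is ``x``
    itself, the remaining columns are the restricted truncated-power terms.
    All nonlinear columns vanish for ``x <= k_1``.
    """
    x, k = _prep(x, spec)
    K = len(k)
    out = np.empty(x.shape + (K - 1,), dtype=float)
    out[..., 0] = x
    if K == 2:
        return out
    k1, kK = k[0], k[-1]
    d1 = np.maximum(x - k1, 0.0) ** 3
    dK = np.maximum(x - kK, 0.0) ** 3
    for j in range(1, K - 1):
        lam = (kK - k[j]) / (kK - k1)
        out[..., j] = np.maximum(x - k[j], 0.0) ** 3 - lam * d1 - (1.0 - lam) * dK
    return out


def rcs_deriv(x, spec: SplineSpec) -> np.ndarray:
    """Elementwise derivative of :func:`rcs_basis` with respect to ``x``."""
    x, k = _prep(x, spec)
    K = len(k)
    out = np.empty(x.shape + (K - 1,), dtype=float)
    out[..., 0] = 1.0
    if K == 2:
        return out
    k1, kK = k[0], k[-1]
    d1 = 3.0 * np.maximum(x - k1, 0.0) ** 2
    dK = 3.0 * np.maximum(x - kK, 0.0) ** 2
    for j in range(1, K - 1):
        lam = (kK - k[j]) / (kK - k1)
        out[..., j] = 3.0 * np.maximum(x - k[j], 0.0) ** 2 - lam * d1 - (1.0 - lam) * dK
    return out


def knots_from_quantiles(
    values,
    df: int,
    *,
    boundary_quantiles: tuple[float, float] = (0.0, 1.0),
) -> SplineSpec:
    """Place ``df + 1`` knots at quantiles of observed values.

    Boundary knots sit at ``boundary_quantiles`` of the data; interior knots
    at equally spaced quantiles in between.  Duplicate quantiles (heavily
    tied data) are collapsed, reducing the effective degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot place knots on an empty sample")
    if df < 1:
        raise ValueError("df must be >= 1")
    lo, hi = boundary_quantiles
    qs = np.linspace(lo, hi, df + 1)
    knots = np.unique(np.quantile(values, qs))
    if len(knots) < 2:
        raise ValueError(
            "degenerate sample: all quantile knots coincide "
            f"(value {knots[0]!r}); cannot build a spline basis"
        )
    return SplineSpec(tuple(knots))
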