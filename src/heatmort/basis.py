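"""Natural cubic spline bases and the temperature x lag cross-basis.

A distributed-lag non-linear model (DLNM) represents the exposure-lag-response
surface as a tensor product of two one-dimensional bases: a natural cubic
spline in the exposure (daily mean temperature) and a second natural cubic
spline in the lag dimension.  The design row for day *t* is the sum over lags

    w_t = sum_{l=0..L} b_var(x_{t-l}) (x) b_lag(l)

so that the fitted linear predictor ``w_t . beta`` is the accumulated
contribution of the last ``L+1`` days of exposure.

Natural cubic splines are cubic splines constrained to have zero second
derivative at (and hence be linear beyond) the boundary knots.  This tail
linearity is what later allows log-linear extrapolation of the fitted
exposure-response curve to temperatures never observed historically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "NaturalCubicSpline",
    "natural_cubic_basis",
    "KnotSpec",
    "CrossBasis",
    "build_crossbasis",
]


class NaturalCubicSpline:
    """Natural cubic spline basis on given internal knots and boundary.

    Columns span the space of natural cubic splines (modulo an intercept when
    ``intercept=False``).  The basis is built from a cubic B-spline design on
    the augmented knot sequence, projected onto the null space of the
    second-derivative constraints at the two boundary knots, which enforces
    linearity outside the boundary.  Evaluation beyond the boundary uses the
    exact first-order Taylor extension (the spline itself is linear there).

    Parameters
    ----------
    internal_knots : array-like
        Knot locations strictly inside ``boundary``.  May be empty.
    boundary : (float, float)
        Boundary knots ``lo < hi``.
    intercept : bool
        If False (default) the constant function is removed from the span and
        the basis has ``len(internal_knots) + 1`` columns; if True it has
        ``len(internal_knots) + 2``.
    """

    def __init__(self, internal_knots, boundary, intercept: bool = False):
        lo, hi = float(boundary[0]), float(boundary[1])
        if not lo < hi:
            raise ValueError(f"boundary must satisfy lo < hi, got ({lo}, {hi})")
        knots = np.sort(np.asarray(internal_knots, dtype=float))
        if knots.size and (knots.min() <= lo or knots.max() >= hi):
            raise ValueError(
                "internal knots must lie strictly inside the boundary "
                f"({lo}, {hi}); got {knots}"
            )
        self.internal_knots = knots
        self.boundary = (lo, hi)
        self.intercept = bool(intercept)

        t = np.concatenate([[lo] * 4, knots, [hi] * 4])
        n_b = len(t) - 4  # number of cubic B-spline columns
        self._bspl = BSpline(t, np.eye(n_b), 3, extrapolate=False)
        # Second-derivative rows at the boundaries; their null space is the
        # natural-spline subspace.
        const = self._bspl.derivative(2)(np.array([lo, hi]))
        self._drop0 = not self.intercept
        if self._drop0:
            const = const[:, 1:]
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._null = q[:, 2:]  # (n_b[-1] x df)
        self.df = self._null.shape[1]

    def _raw(self, x: np.ndarray, nu: int = 0) -> np.ndarray:
        b = self._bspl if nu == 0 else self._bspl.derivative(nu)
        out = b(x)
        return out[:, 1:] if self._drop0 else out

    def __call__(self, x) -> np.ndarray:
        """Evaluate the basis at ``x`` -> array of shape ``(len(x), df)``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary
        inner = np.clip(x, lo, hi)
        design = self._raw(inner) @ self._null
        # Linear Taylor extension beyond the boundary (exact for a natural
        # spline, whose second derivative vanishes there).
        for bound, mask in ((lo, x < lo), (hi, x > hi)):
            if mask.any():
                b0 = self._raw(np.array([bound])) @ self._null
                b1 = self._raw(np.array([bound]), nu=1) @ self._null
                design[mask] = b0 + (x[mask] - bound)[:, None] * b1
        return design

    def derivative(self, x) -> np.ndarray:
        """First derivative of each basis column at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary
        inner = np.clip(x, lo, hi)
        d = self._raw(inner, nu=1) @ self._null
        for bound, mask in ((lo, x < lo), (hi, x > hi)):
            if mask.any():
                d[mask] = self._raw(np.array([bound]), nu=1) @ self._null
        return d

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"NaturalCubicSpline(knots={self.internal_knots.tolist()}, "
            f"boundary={self.boundary}, intercept={self.intercept}, df={self.df})"
        )


def natural_cubic_basis(x, internal_knots, boundary, intercept: bool = False):
    """Natural cubic spline design matrix (no intercept column by default).

    Returns an ``(len(x), df)`` array with ``df = len(internal_knots) + 1``
    (``+ 2`` with ``intercept=True``).  Values beyond ``boundary`` continue
    linearly.
    """
    return NaturalCubicSpline(internal_knots, boundary, intercept=intercept)(x)


def _log_spaced_lag_knots(lag_max: int, n_knots: int = 2) -> np.ndarray:
    """Internal lag knots equally spaced on the log scale over [1, lag_max]."""
    if lag_max < 2 or n_knots < 1:
        return np.array([])
    return np.exp(np.linspace(0.0, np.log(lag_max), n_knots + 2))[1:-1]


@dataclass(frozen=True)
class KnotSpec:
    """Knot placement for the exposure and lag dimensions of the cross-basis.

    ``var_knots`` are actual temperatures (degrees C); they are conventionally
    placed at percentiles of the in-season exposure distribution (default
    10/25/50/75/90th) with boundary knots at the observed range.  The lag basis
    is a natural cubic spline over ``[0, lag_max]`` with an intercept and
    internal knots equally spaced on the log-lag scale, so that more
    flexibility is spent on short lags where effects change fastest.
    """

    var_knots: tuple = ()
    var_boundary: tuple = (0.0, 1.0)
    lag_max: int = 10
    lag_knots: tuple = None
    lag_intercept: bool = True
    var_knot_percentiles: tuple = None  # provenance only

    def __post_init__(self):
        if self.lag_max < 0:
            raise ValueError("lag_max must be >= 0")
        lo, hi = self.var_boundary
        if not lo < hi:
            raise ValueError("var_boundary must satisfy lo < hi")
        ks = tuple(float(k) for k in self.var_knots)
        if any(not lo < k < hi for k in ks):
            raise ValueError("var_knots must lie strictly inside var_boundary")
        if self.lag_knots is None:
            object.__setattr__(
                self, "lag_knots", tuple(_log_spaced_lag_knots(self.lag_max))
            )
        if self.var_knot_percentiles is not None:
            pcts = tuple(self.var_knot_percentiles)
            if list(pcts) != sorted(pcts) or any(not 0 < p < 100 for p in pcts):
                raise ValueError("percentiles must be increasing in (0, 100)")

    @classmethod
    def from_temperatures(
        cls,
        temps,
        percentiles=(10, 25, 50, 75, 90),
        lag_max: int = 10,
        lag_knots=None,
        lag_intercept: bool = True,
    ) -> "KnotSpec":
        """Place exposure knots at percentiles of an observed series.

        ``temps`` should be the pooled in-season temperature distribution;
        boundary knots go at the observed min/max.
        """
        t = np.asarray(temps, dtype=float)
        t = t[np.isfinite(t)]
        if t.size == 0:
            raise ValueError("no finite temperatures to place knots on")
        pcts = tuple(sorted(percentiles))
        knots = tuple(np.percentile(t, pcts))
        return cls(
            var_knots=knots,
            var_boundary=(float(t.min()), float(t.max())),
            lag_max=lag_max,
            lag_knots=lag_knots,
            lag_intercept=lag_intercept,
            var_knot_percentiles=pcts,
        )

    def var_basis(self) -> NaturalCubicSpline:
        return NaturalCubicSpline(self.var_knots, self.var_boundary, intercept=False)

    def lag_basis_matrix(self) -> np.ndarray:
        """Lag basis evaluated at lags 0..lag_max -> (lag_max+1, df_lag).

        With ``lag_max == 0`` the lag dimension degenerates to a single
        intercept column.
        """
        lags = np.arange(self.lag_max + 1, dtype=float)
        if self.lag_max == 0 or (len(self.lag_knots) == 0 and self.lag_max < 1):
            return np.ones((1, 1))
        if len(self.lag_knots) == 0:
            # no internal knots: linear (+ intercept) in lag
            b = NaturalCubicSpline([], (0.0, float(self.lag_max)),
                                   intercept=self.lag_intercept)
            return b(lags)
        b = NaturalCubicSpline(
            self.lag_knots, (0.0, float(self.lag_max)), intercept=self.lag_intercept
        )
        return b(lags)

    @property
    def df_var(self) -> int:
        return len(self.var_knots) + 1

    @property
    def df_lag(self) -> int:
        return self.lag_basis_matrix().shape[1]


@dataclass
class CrossBasis:
    """Tensor-product design matrix for the DLNM.

    ``matrix`` has one row per observation and ``df_var * df_lag`` columns,
    ordered with the exposure (var) index varying fastest: column
    ``k * df_var + j`` pairs lag-basis column ``k`` with var-basis column
    ``j``.  ``valid`` flags rows whose full lag window lies within the same
    unit with no date gaps; invalid rows are zero-filled and must be excluded
    from any fit.
    """

    matrix: np.ndarray
    valid: np.ndarray
    spec: KnotSpec
    exposure: np.ndarray
    units: np.ndarray = None

    @property
    def df_var(self) -> int:
        return self.spec.df_var

    @property
    def df_lag(self) -> int:
        return self.spec.df_lag

    def __len__(self) -> int:
        return self.matrix.shape[0]


def _segment_ids(units, dates) -> np.ndarray:
    """Contiguous-run ids: a new segment starts at each unit change or date gap."""
    n = len(units)
    if n == 0:
        return np.array([], dtype=int)
    new = np.ones(n, dtype=bool)
    if n > 1:
        same_unit = np.asarray(units[1:]) == np.asarray(units[:-1])
        if dates is not None:
            d = pd.to_datetime(np.asarray(dates))
            step = (d[1:] - d[:-1]).days == 1
        else:
            step = np.ones(n - 1, dtype=bool)
        new[1:] = ~(same_unit & step)
    return np.cumsum(new) - 1


def build_crossbasis(series, spec: KnotSpec, units=None, dates=None) -> CrossBasis:
    """Build the temperature x lag cross-basis from per-unit exposure series.

    Parameters
    ----------
    series : array-like
        Exposure values in time order.  Multiple units may be concatenated;
        pass ``units`` (and ideally ``dates``) so lag windows never leak
        across unit boundaries or across gaps in the record.
    spec : KnotSpec
    units, dates : array-like, optional
        Per-observation unit labels and calendar dates aligned with
        ``series``.  Rows whose ``lag_max`` look-back crosses a segment
        boundary are flagged invalid.

    Returns
    -------
    CrossBasis
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    L = spec.lag_max
    if units is None:
        units = np.zeros(n, dtype=int)
    units = np.asarray(units)
    seg = _segment_ids(units, dates)
    seg_lengths = np.bincount(seg) if n else np.array([])
    if n and seg_lengths.min() < L + 1:
        raise ValueError(
            f"every per-unit series must have at least lag_max+1 = {L + 1} "
            f"consecutive days; shortest segment has {int(seg_lengths.min())}"
        )

    # lagged exposure matrix, NaN where the lag crosses a segment boundary
    pos = np.arange(n) - np.concatenate([[0], np.cumsum(seg_lengths)])[seg]
    xlag = np.full((n, L + 1), np.nan)
    idx = np.arange(n)
    for lag in range(L + 1):
        ok = pos >= lag
        xlag[ok, lag] = x[idx[ok] - lag]
    valid = ~np.isnan(xlag).any(axis=1)

    vb = spec.var_basis()
    C = spec.lag_basis_matrix()  # (L+1, df_lag)
    V = np.zeros((n, L + 1, spec.df_var))
    V[valid] = vb(xlag[valid].ravel()).reshape(-1, L + 1, spec.df_var)
    # column k*df_var + j  <-  sum_l V[t,l,j] * C[l,k]   (var index fastest)
    mat = np.einsum("tlj,lk->tkj", V, C).reshape(n, spec.df_lag * spec.df_var)
    mat[~valid] = 0.0
    return CrossBasis(matrix=mat, valid=valid, spec=spec, exposure=x, units=units)
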