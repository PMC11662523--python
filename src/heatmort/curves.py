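"""Exposure-response curves, MMT location and lag-dimension reduction.

All risk summaries are differences of linear predictors, so a curve is fully
determined by the fitted coefficients, their covariance, and the chosen
reference temperature.  The minimum mortality temperature (MMT) is the grid
temperature at which the overall cumulative log relative risk attains its
minimum; it becomes the reference for every relative risk and for the
attributable-fraction calculations downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basis import KnotSpec
from .fit import FitResult

__all__ = [
    "ExposureResponseCurve",
    "ReducedFit",
    "predict_cumulative",
    "reduce_to_overall",
    "find_mmt",
    "MMTResult",
    "percent_increase",
    "extrapolate_curve",
    "cumulative_log_rr",
    "lag_response",
]

logger = logging.getLogger("heatmort")

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ExposureResponseCurve:
    """Overall cumulative exposure-response curve centred at ``reference``."""

    temp_grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference: float

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_lo(self) -> np.ndarray:
        return np.exp(self.log_rr - Z975 * self.se)

    @property
    def rr_hi(self) -> np.ndarray:
        return np.exp(self.log_rr + Z975 * self.se)


@dataclass
class ReducedFit:
    """Overall cumulative association on the exposure basis alone.

    ``eta = M beta`` where ``M`` sums the lag basis over lags 0..L; the
    cumulative log RR between two temperatures is then a plain basis
    difference dotted with ``eta``, which makes attribution and projection
    cheap and makes Monte Carlo coefficient draws low-dimensional.
    """

    eta: np.ndarray
    vcov_eta: np.ndarray
    spec: KnotSpec


def _lag_sum_weights(spec: KnotSpec) -> np.ndarray:
    return spec.lag_basis_matrix().sum(axis=0)


def _reduction_matrix(spec: KnotSpec) -> np.ndarray:
    # column ordering of the cross-basis is var-fastest: col = k*df_var + j
    s = _lag_sum_weights(spec)
    return np.kron(s[None, :], np.eye(spec.df_var)).reshape(spec.df_var, -1)


def reduce_to_overall(fit: FitResult, spec: KnotSpec) -> ReducedFit:
    """Collapse cross-basis coefficients to the exposure dimension.

    The reduced coefficients reproduce the full fit's cumulative predictions
    exactly (the map is linear), with covariance ``M V M'``.
    """
    M = _reduction_matrix(spec)
    eta = M @ fit.beta
    vcov_eta = M @ fit.vcov @ M.T
    return ReducedFit(eta=eta, vcov_eta=(vcov_eta + vcov_eta.T) / 2, spec=spec)


def predict_cumulative(fit: FitResult, spec: KnotSpec, temp_grid,
                       reference: float) -> ExposureResponseCurve:
    """Cumulative (lag-summed) RR versus ``reference`` on a temperature grid.

    ``log_rr(T) = [ (b_var(T) - b_var(ref)) (x) sum_l b_lag(l) ] . beta``
    with delta-method standard errors from the fitted covariance.
    """
    grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("temperature grid is empty")
    red = reduce_to_overall(fit, spec)
    return _curve_from_reduced(red, grid, reference)


def _curve_from_reduced(red: ReducedFit, grid: np.ndarray,
                        reference: float) -> ExposureResponseCurve:
    vb = red.spec.var_basis()
    D = vb(grid) - vb([reference])  # broadcast subtract the reference row
    log_rr = D @ red.eta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, red.vcov_eta, D), 0.0))
    at_ref = np.isclose(grid, reference)
    log_rr[at_ref] = 0.0
    se[at_ref] = 0.0
    return ExposureResponseCurve(temp_grid=grid, log_rr=log_rr, se=se,
                                 reference=float(reference))


def curve_from_reduced(red: ReducedFit, temp_grid, reference: float
                       ) -> ExposureResponseCurve:
    """Cumulative curve straight from a ReducedFit (equals the full-fit one)."""
    grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("temperature grid is empty")
    return _curve_from_reduced(red, grid, reference)


@dataclass
class MMTResult:
    mmt: float
    at_boundary: bool


def find_mmt(fit: FitResult, spec: KnotSpec, search_range,
             step: float = 0.1, provisional_reference: float = None) -> MMTResult:
    """Locate the minimum mortality temperature on a fine grid.

    Two-pass: predict the cumulative curve centred at a provisional reference
    (the midpoint of the search window unless given, conventionally the
    in-season median), re-centre at the minimiser and repeat once.  The
    conditional fit itself is centre-invariant, so the passes agree; both are
    kept for transparency.  A minimiser on the window edge is returned with
    ``at_boundary=True``.
    """
    lo, hi = float(search_range[0]), float(search_range[1])
    if not lo < hi:
        raise ValueError("search range must satisfy lo < hi")
    grid = np.arange(lo, hi + step / 2, step)
    ref = (lo + hi) / 2 if provisional_reference is None else provisional_reference
    for _ in range(2):
        curve = predict_cumulative(fit, spec, grid, ref)
        ref = float(grid[np.argmin(curve.log_rr)])
    at_edge = bool(np.isclose(ref, grid[0]) or np.isclose(ref, grid[-1]))
    if at_edge:
        logger.warning("MMT search hit the window edge at %.2f degC", ref)
    return MMTResult(mmt=ref, at_boundary=at_edge)


def percent_increase(rr) -> float:
    """Relative risk expressed as percent increase: (RR - 1) * 100."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risk must be positive")
    out = (rr - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def cumulative_log_rr(red: ReducedFit, temps, reference: float) -> np.ndarray:
    """Cumulative log RR at arbitrary temperatures versus the reference.

    Temperatures beyond the boundary knots are handled by the natural
    spline's linear tails, i.e. the curve is log-linearly extrapolated with
    the slope it has at the boundary.
    """
    vb = red.spec.var_basis()
    temps = np.atleast_1d(np.asarray(temps, dtype=float))
    return (vb(temps) - vb([reference])) @ red.eta


def extrapolate_curve(red: ReducedFit, temps, reference: float) -> np.ndarray:
    """Log-linear extension of the cumulative curve beyond the observed range.

    For T above the upper boundary knot the log RR continues linearly with
    the boundary slope of the natural cubic spline (its exact tail
    behaviour); values within the range are unchanged.  Alias of
    :func:`cumulative_log_rr`, kept as an explicit named operation.
    """
    return cumulative_log_rr(red, temps, reference)


def lag_response(fit: FitResult, spec: KnotSpec, temp: float,
                 reference: float):
    """Lag-specific RR at a given temperature versus the reference.

    Returns ``(rr, rr_lo, rr_hi)`` arrays over lags 0..lag_max.  The per-lag
    log RRs sum to the cumulative log RR at the same temperature.
    """
    vb = spec.var_basis()
    dv = (vb([temp]) - vb([reference]))[0]          # (df_var,)
    C = spec.lag_basis_matrix()                      # (L+1, df_lag)
    # row for lag l: kron(C[l], dv) under var-fastest ordering
    rows = np.einsum("lk,j->lkj", C, dv).reshape(C.shape[0], -1)
    log_rr = rows @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, fit.vcov, rows), 0.0))
    return np.exp(log_rr), np.exp(log_rr - Z975 * se), np.exp(log_rr + Z975 * se)
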