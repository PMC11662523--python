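"""Case time series strata and conditional Poisson regression.

The case time series design analyses many small-area daily series jointly by
conditioning out stratum-specific baseline rates: with strata defined as
unit x year x month (default), each stratum's vector of daily counts, given
its total, is multinomial with cell probabilities proportional to
``exp(w_t . beta)``.  Maximising this conditional likelihood is equivalent to
a Poisson regression with one indicator per stratum, but never forms the
(huge) indicator design, and it absorbs long-term and seasonal trends in the
baseline at the finest spatial scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import CrossBasis

__all__ = ["StratumIndex", "FitResult", "assign_strata", "fit_conditional_poisson"]

logger = logging.getLogger("heatmort")

FULL_SCHEME = "unit-year-month"
REDUCED_SCHEME = "unit-year"


class FitError(RuntimeError):
    """Raised when the conditional likelihood has no information to fit."""


@dataclass
class StratumIndex:
    """Stratum assignment: integer codes plus human-readable labels.

    ``codes`` is -1 for records excluded from the likelihood (invalid lag
    windows).  Strata never span units.
    """

    codes: np.ndarray
    labels: np.ndarray  # label per stratum code
    scheme: str

    @property
    def n_strata(self) -> int:
        return len(self.labels)


def assign_strata(panel: pd.DataFrame, scheme: str = FULL_SCHEME,
                  valid=None) -> StratumIndex:
    """Label each record with its baseline stratum.

    Parameters
    ----------
    panel : DataFrame with columns ``unit`` and ``date``.
    scheme : ``"unit-year-month"`` (default) or ``"unit-year"``.
    valid : optional boolean mask; records flagged False (e.g. by the
        cross-basis) get code -1 and are excluded.
    """
    dates = pd.to_datetime(panel["date"])
    unit = panel["unit"].astype(str)
    if scheme == FULL_SCHEME:
        labels = (unit + ":" + dates.dt.year.astype(str)
                  + ":" + dates.dt.month.astype(str).str.zfill(2))
    elif scheme == REDUCED_SCHEME:
        labels = unit + ":" + dates.dt.year.astype(str)
    else:
        raise ValueError(f"unknown stratum scheme {scheme!r}")
    if valid is None:
        valid = np.ones(len(panel), dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    uniq, codes = np.unique(labels[valid], return_inverse=True)
    full_codes = np.full(len(panel), -1, dtype=int)
    full_codes[valid] = codes
    return StratumIndex(codes=full_codes, labels=uniq, scheme=scheme)


@dataclass
class FitResult:
    """Conditional Poisson fit of daily deaths on the cross-basis.

    ``beta`` are the cross-basis coefficients, ``vcov`` the inverse observed
    information at the optimum (the covariance sampled when building Monte
    Carlo empirical confidence intervals).
    """

    beta: np.ndarray
    vcov: np.ndarray
    n_strata_total: int
    n_strata_informative: int
    loglik: float
    converged: bool
    n_iter: int = 0

    def __post_init__(self):
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise ValueError("vcov must be symmetric")


def _stratum_sums(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts, axis=0)


def fit_conditional_poisson(
    crossbasis,
    deaths,
    strata: StratumIndex,
    max_iter: int = 100,
    tol_loglik: float = 1e-9,
    tol_grad: float = 1e-6,
) -> FitResult:
    """Maximise the conditional (multinomial) Poisson likelihood.

    Within each stratum *s* with daily counts ``y_i`` and design rows
    ``x_i``, the conditional log-likelihood term is
    ``sum_i y_i x_i.beta - Y_s log sum_i exp(x_i.beta)``; strata with zero
    total deaths (or a single record) are uninformative and contribute
    nothing.  Newton-Raphson with step-halving; the covariance is the inverse
    observed information at the optimum.

    Parameters
    ----------
    crossbasis : CrossBasis or (n, p) design array
    deaths : (n,) non-negative integer counts
    strata : StratumIndex aligned with the design rows

    Raises
    ------
    FitError
        If no stratum carries information (all totals zero).
    """
    if isinstance(crossbasis, CrossBasis):
        X_all = crossbasis.matrix
        base_valid = crossbasis.valid
    else:
        X_all = np.asarray(crossbasis, dtype=float)
        base_valid = np.ones(X_all.shape[0], dtype=bool)
    y_all = np.asarray(deaths, dtype=float)
    if np.any(y_all < 0) or np.any(y_all != np.round(y_all)):
        raise ValueError("deaths must be non-negative integers")
    codes = strata.codes
    keep = base_valid & (codes >= 0)

    X, y, c = X_all[keep], y_all[keep], codes[keep]
    order = np.argsort(c, kind="stable")
    X, y, c = X[order], y[order], c[order]
    starts = np.concatenate([[0], 1 + np.flatnonzero(np.diff(c))]) if len(c) else np.array([0])
    sizes = np.diff(np.concatenate([starts, [len(c)]]))
    totals = _stratum_sums(y, starts)

    informative = (totals > 0) & (sizes > 1)
    n_total = len(totals)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise FitError("no informative strata (all stratum totals are zero)")

    keep_rows = np.repeat(informative, sizes)
    X, y = X[keep_rows], y[keep_rows]
    sizes = sizes[informative]
    totals = totals[informative]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    Ys_row = np.repeat(totals, sizes)

    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    logger.info(
        "conditional Poisson fit: %d rows, %d columns, %d/%d informative strata",
        X.shape[0], p_dim, n_inf, n_total,
    )

    def loglik_parts(b):
        eta = X @ b
        m = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - np.repeat(m, sizes))
        denom = _stratum_sums(w, starts)
        ll = float(y @ eta - totals @ (np.log(denom) + m))
        p = w / np.repeat(denom, sizes)
        return ll, p

    ll, p = loglik_parts(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wrow = Ys_row * p
        grad = X.T @ y - X.T @ wrow
        xbar = _stratum_sums(p[:, None] * X, starts)            # (S, p)
        info = (X * wrow[:, None]).T @ X - (xbar * totals[:, None]).T @ xbar
        # pinv handles flat likelihood directions (e.g. stratum-constant
        # columns, whose gradient and information row are identically zero)
        step = np.linalg.pinv(info, rcond=1e-12, hermitian=True) @ grad
        # step-halving
        new_ll, new_p = loglik_parts(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll, new_p = loglik_parts(beta + step)
        beta = beta + step
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll, p = new_ll, new_p
        wrow = Ys_row * p
        grad = X.T @ y - X.T @ wrow
        if rel < tol_loglik and np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
    if not converged:
        logger.warning("conditional Poisson fit did not converge in %d iterations",
                       max_iter)

    xbar = _stratum_sums(p[:, None] * X, starts)
    info = (X * (Ys_row * p)[:, None]).T @ X - (xbar * totals[:, None]).T @ xbar
    if np.linalg.cond(info) < 1e12:
        vcov = np.linalg.inv(info)
    else:
        logger.warning("observed information (near-)singular; using pseudo-inverse")
        vcov = np.linalg.pinv(info, rcond=1e-12, hermitian=True)
    vcov = (vcov + vcov.T) / 2.0

    logger.info("fit %s after %d iterations, loglik=%.6f",
                "converged" if converged else "NOT converged", it, ll)
    return FitResult(
        beta=beta, vcov=vcov, n_strata_total=n_total,
        n_strata_informative=n_inf, loglik=ll, converged=converged, n_iter=it,
    )
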