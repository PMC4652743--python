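"""Limiting-dilution digital quantitation.

In a dilution series, the fraction of positive RT-PCR reactions at relative
dilution ``d`` of a one-cell-equivalent lysate follows the Poisson zero-class
model ``p(d) = 1 - exp(-lambda * d)``; the per-cell copy number ``lambda`` is
recovered by least squares on the positive-reaction frequencies.  Close
adherence of the data to this curve is the accepted demonstration of
single-molecule detection sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConfigError, DataError

__all__ = ["DilutionSeries", "LambdaFit", "fit_lambda", "poisson_error", "poisson_gof",
           "read_dilution_csv", "default_dilution_ladder"]


@dataclass
class DilutionSeries:
    """Digital readouts: (dilution factor d, positives k, reactions n) rows."""

    target: str
    d: np.ndarray
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.k = np.asarray(self.k, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.d.size == 0:
            raise ConfigError("dilution series must contain at least one row")
        if not (self.d.size == self.k.size == self.n.size):
            raise DataError("d, k, n must have equal length")
        if np.any((self.d <= 0) | (self.d > 1)):
            raise DataError("dilution factors must lie in (0, 1]")
        if np.any(self.n < 1):
            raise DataError("each dilution needs at least one reaction")
        if np.any((self.k < 0) | (self.k > self.n)):
            raise DataError("positives must satisfy 0 <= k <= n")

    @property
    def frequency(self) -> np.ndarray:
        return self.k / self.n


@dataclass
class LambdaFit:
    """Least-squares Poisson fit of a dilution series."""

    target: str
    lambda_hat: float
    residual_ss: float
    predicted: np.ndarray
    freq_se: np.ndarray
    lower_bound: bool = False
    weighted: bool = field(default=False, repr=False)


def poisson_error(k, n):
    """Poisson error estimate of a positive-reaction frequency: ``sqrt(k)/n``,
    with a one-count floor ``1/n`` when no reaction was positive."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise DataError("n must be positive")
    if np.any((k < 0) | (k > n)):
        raise DataError("k must satisfy 0 <= k <= n")
    se = np.sqrt(np.maximum(k, 1.0)) / n
    return se if se.ndim else float(se)


def _ss(lam, series: DilutionSeries, weights) -> float:
    resid = series.frequency - (1.0 - np.exp(-lam * series.d))
    return float(np.sum(weights * resid * resid))


def fit_lambda(series: DilutionSeries, weighted: bool = False) -> LambdaFit:
    """Fit the per-cell copy number by bounded 1-D least squares.

    Minimises ``sum_d (k_d/n_d - (1 - exp(-lambda d)))^2`` over
    ``lambda >= 0`` (optionally weighted by the inverse squared Poisson
    error).  All-zero series give ``lambda_hat = 0``; fully positive series
    are flagged ``lower_bound`` (the data only bound lambda from below) with
    ``lambda_hat = inf``.
    """
    se = poisson_error(series.k, series.n)
    weights = 1.0 / se**2 if weighted else np.ones_like(series.d)
    if np.all(series.k == 0):
        lam = 0.0
        pred = np.zeros_like(series.d)
        return LambdaFit(series.target, lam, _ss(lam, series, weights), pred, se,
                         weighted=weighted)
    if np.all(series.k == series.n):
        pred = np.ones_like(series.d)
        return LambdaFit(series.target, float("inf"), 0.0, pred, se,
                         lower_bound=True, weighted=weighted)
    # at lambda*d ~ 40 the model saturates to 1 in double precision
    hi = 50.0 / float(np.min(series.d))
    res = minimize_scalar(_ss, bounds=(0.0, hi), args=(series, weights),
                          method="bounded", options={"xatol": 1e-10})
    lam = float(res.x)
    pred = 1.0 - np.exp(-lam * series.d)
    return LambdaFit(series.target, lam, _ss(lam, series, weights), pred, se,
                     weighted=weighted)


def poisson_gof(series: DilutionSeries, fit: LambdaFit | None = None,
                n_boot: int = 500, rng=None) -> float:
    """Parametric-bootstrap goodness-of-fit p-value.

    Simulates ``k* ~ Binomial(n, p(lambda_hat))`` per dilution, refits lambda,
    and compares the refitted residual sum of squares with the observed one:
    ``p = (1 + #{ss* >= ss_obs}) / (n_boot + 1)``.  Single-row series return
    1 by convention (no residual degrees of freedom).
    """
    if fit is None:
        fit = fit_lambda(series)
    if series.d.size < 2 or fit.lower_bound:
        return 1.0
    rng = np.random.default_rng(rng)
    weights = np.ones_like(series.d)
    p_model = 1.0 - np.exp(-fit.lambda_hat * series.d)
    ss_obs = fit.residual_ss
    count = 0
    for _ in range(n_boot):
        k_star = rng.binomial(series.n, p_model)
        boot = DilutionSeries(series.target, series.d, k_star, series.n)
        bfit = fit_lambda(boot)
        if bfit.lower_bound:
            ss_star = _ss(50.0 / float(np.min(series.d)), boot, weights)
        else:
            ss_star = bfit.residual_ss
        if ss_star >= ss_obs - 1e-15:
            count += 1
    return (1.0 + count) / (n_boot + 1.0)


def read_dilution_csv(path) -> list[DilutionSeries]:
    """Read series from a CSV with columns target,d,k,n (one row per dilution)."""
    df = pd.read_csv(path)
    missing = [c for c in ("target", "d", "k", "n") if c not in df.columns]
    if missing:
        raise DataError(f"dilution CSV missing column(s): {', '.join(missing)}")
    out = []
    for target, grp in df.groupby("target", sort=False):
        out.append(DilutionSeries(str(target), grp["d"].to_numpy(),
                                  grp["k"].to_numpy(), grp["n"].to_numpy()))
    return out


def default_dilution_ladder(steps: int = 9) -> np.ndarray:
    """Two-fold serial dilutions 1, 1/2, ..., 1/2**(steps-1)."""
    return 0.5 ** np.arange(steps)
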