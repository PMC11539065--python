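"""First-order aggregation kinetics: monomer loss M(t) = M0·exp(−kobs·t).

The observable is % monomer retained (relative to an undegraded standard)
versus incubation time in days; the initial aggregation rate is
v = M0·kobs (% day⁻¹), reported alongside ln v as in stability summaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class MonomerLossSeries:
    times: np.ndarray                 # days, increasing
    monomer: np.ndarray               # % of undegraded standard

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.monomer = np.asarray(self.monomer, dtype=float)
        if len(self.times) != len(self.monomer):
            raise ValueError("time and monomer lengths differ")
        if len(self.times) < 3:
            raise ValueError("need at least 3 timepoints")
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be non-negative and increasing")
        if not np.all(np.isfinite(self.monomer)):
            raise ValueError("monomer values must be finite")


class FirstOrderDecayModel(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for single-exponential monomer loss.

    Fitted attributes: ``M0_`` (%), ``kobs_`` (day⁻¹, bounded ≥ 0), ``v_``
    (= M0_·kobs_, % day⁻¹), ``ln_v_`` (None when v ≤ 0), ``M0_sem_`` and
    ``kobs_sem_`` from the fit covariance.

    ``with_offset=True`` adds a plateau term M(t) = (M0−c)·exp(−kt)+c; it is
    off by default because the model names only M0, kobs, M and t.
    """

    def __init__(self, with_offset: bool = False):
        self.with_offset = with_offset

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        m = np.asarray(y, dtype=float).ravel()
        if len(t) != len(m):
            raise ValueError("time and monomer lengths differ")
        if len(t) < 3:
            raise ValueError("need at least 3 timepoints")

        m0_0 = max(float(m[0]), 1e-9)
        # crude log-linear slope for the rate guess
        pos = m > 0
        if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
            slope = np.polyfit(t[pos], np.log(m[pos]), 1)[0]
            k0 = max(-float(slope), 0.0)
        else:
            k0 = 0.1

        if self.with_offset:
            def resid(p):
                M0, k, c = p
                return (M0 - c) * np.exp(-k * t) + c - m
            x0 = np.array([m0_0, max(k0, 1e-6), 0.0])
            lb, ub = [0, 0, -np.inf], [np.inf, np.inf, np.inf]
        else:
            def resid(p):
                M0, k = p
                return M0 * np.exp(-k * t) - m
            x0 = np.array([m0_0, max(k0, 1e-6)])
            lb, ub = [0, 0], [np.inf, np.inf]
        res = least_squares(resid, x0, bounds=(lb, ub), method="trf")

        self.M0_ = float(res.x[0])
        self.kobs_ = float(res.x[1])
        self.offset_ = float(res.x[2]) if self.with_offset else 0.0
        if self.kobs_ <= 1e-12 and np.polyfit(t, m, 1)[0] > 0:
            warnings.warn(
                "monomer trend increases; kobs pinned at 0", stacklevel=2
            )
            self.kobs_ = 0.0
        self.v_ = self.M0_ * self.kobs_
        self.ln_v_ = float(np.log(self.v_)) if self.v_ > 0 else None

        # parameter SEMs from the Jacobian at the optimum
        dof = max(len(t) - len(res.x), 1)
        s2 = 2 * res.cost / dof
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            sems = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            sems = np.full(len(res.x), np.nan)
        self.M0_sem_ = float(sems[0])
        self.kobs_sem_ = float(sems[1])
        self.residual_norm_ = float(np.sqrt(2 * res.cost))
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        return (self.M0_ - self.offset_) * np.exp(-self.kobs_ * t) + self.offset_


@dataclass
class FirstOrderFit:
    M0: float                         # %
    kobs: float                       # day⁻¹
    v: float                          # % day⁻¹, = M0·kobs
    ln_v: float | None
    M0_sem: float
    kobs_sem: float
    residual_norm: float


def fit_first_order(series: MonomerLossSeries) -> FirstOrderFit:
    """Nonlinear least squares of M(t) = M0·exp(−kobs·t), both parameters
    free (kobs bounded at 0)."""
    model = FirstOrderDecayModel().fit(series.times, series.monomer)
    return FirstOrderFit(
        M0=model.M0_,
        kobs=model.kobs_,
        v=model.v_,
        ln_v=model.ln_v_,
        M0_sem=model.M0_sem_,
        kobs_sem=model.kobs_sem_,
        residual_norm=model.residual_norm_,
    )


def initial_rate(fit: FirstOrderFit) -> tuple[float, float | None]:
    """Initial aggregation rate v = M0·kobs at t = 0 and its natural log
    (v in % day⁻¹); ln v is None (flagged undefined) when v ≤ 0."""
    v = fit.M0 * fit.kobs
    return v, (float(np.log(v)) if v > 0 else None)


def summarize_replicates(fits: list[FirstOrderFit]) -> pd.DataFrame:
    """ln v mean and SEM across replicate fits (stability-table style)."""
    lnv = np.asarray([f.ln_v for f in fits if f.ln_v is not None])
    return pd.DataFrame({
        "ln_v": {
            "mean": lnv.mean() if len(lnv) else np.nan,
            "sem": (lnv.std(ddof=1) / np.sqrt(len(lnv))) if len(lnv) > 1 else np.nan,
            "n": len(lnv),
        }
    }).T
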