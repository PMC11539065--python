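"""Two-state van't Hoff analysis of fluorescence melting curves.

The folding reporter is the barycentric mean (BCM) of the intrinsic
fluorescence spectrum over the 280–460 nm window.  BCM(T) is fit to the
two-state model

    I(T) = [I_N(T) + I_D(T)·K(T)] / [1 + K(T)],
    K(T) = exp[−(ΔHvh/R)(1/T − 1/Tm)],

where I_N and I_D are the native and denatured state signals (flat or sloped
linear baselines) and R = 8.314 J mol⁻¹ K⁻¹.  At the fitted Tm the unfolded
fraction is 0.5 by construction, and ΔSvh = ΔHvh/Tm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

R_GAS_KJ = 8.314e-3  # kJ/(mol K)
BCM_WINDOW_NM = (280.0, 460.0)


def c_to_k(t_celsius):
    return np.asarray(t_celsius, dtype=float) + 273.15


def k_to_c(t_kelvin):
    return np.asarray(t_kelvin, dtype=float) - 273.15


@dataclass
class FluorescenceMeltSeries:
    """One melting trace: strictly increasing temperatures (K) with either a
    precomputed BCM trace or full spectra (via :func:`bcm_trace`)."""

    temperatures: np.ndarray          # K
    bcm: np.ndarray                   # nm

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.bcm = np.asarray(self.bcm, dtype=float)
        if len(self.temperatures) != len(self.bcm):
            raise ValueError("temperature and BCM lengths differ")
        if len(self.temperatures) < 8:
            raise ValueError("need at least 8 temperature points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")


def barycentric_mean(
    wavelengths: np.ndarray,
    intensities: np.ndarray,
    window: tuple[float, float] = BCM_WINDOW_NM,
) -> float:
    """Intensity-weighted mean emission wavelength Σ(λ·I)/Σ(I) over the
    spectral window."""
    lam = np.asarray(wavelengths, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    mask = (lam >= window[0]) & (lam <= window[1])
    lam, inten = lam[mask], inten[mask]
    total = inten.sum()
    if len(lam) == 0 or total <= 0:
        raise ValueError("no positive intensity inside the BCM window")
    return float((lam * inten).sum() / total)


def bcm_trace(spectra: pd.DataFrame, temperatures_in_celsius: bool | None = None
              ) -> FluorescenceMeltSeries:
    """Collapse a long-format (temperature, wavelength, intensity) table into
    a BCM melting trace.  Temperatures ≤ 150 are treated as °C."""
    temps = []
    bcms = []
    for t, grp in spectra.groupby("temperature", sort=True):
        temps.append(float(t))
        bcms.append(barycentric_mean(grp["wavelength"], grp["intensity"]))
    temps = np.asarray(temps)
    celsius = temperatures_in_celsius
    if celsius is None:
        celsius = bool(np.max(temps) <= 150.0)
    return FluorescenceMeltSeries(
        temperatures=c_to_k(temps) if celsius else temps, bcm=np.asarray(bcms)
    )


def series_from_table(df: pd.DataFrame) -> FluorescenceMeltSeries:
    """Build a series from a table with (temperature, bcm) or spectra columns."""
    if "bcm" in df.columns:
        temps = np.asarray(df["temperature"], dtype=float)
        order = np.argsort(temps)
        temps = temps[order]
        if np.max(temps) <= 150.0:
            temps = c_to_k(temps)
        return FluorescenceMeltSeries(
            temperatures=temps, bcm=np.asarray(df["bcm"], dtype=float)[order]
        )
    return bcm_trace(df)


class TwoStateMeltModel(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the two-state van't Hoff melt.

    Parameters
    ----------
    baseline_mode : 'flat' or 'sloped'
        Whether the native/denatured baselines carry a linear temperature
        slope.  Default flat.
    n_restarts : int
        Jittered restarts around the data-driven initial guess.
    seed : int
        Seed for the restart jitter.

    Fitted attributes: ``Tm_`` (K), ``dHvh_`` (kJ/mol), ``dSvh_``
    (kJ/(mol·K), = dHvh_/Tm_), ``baseline_native_`` / ``baseline_denatured_``
    ((intercept at Tm, slope) pairs), ``residual_norm_``, ``converged_``.
    """

    def __init__(self, baseline_mode: str = "flat", n_restarts: int = 5,
                 seed: int = 0):
        self.baseline_mode = baseline_mode
        self.n_restarts = n_restarts
        self.seed = seed

    @staticmethod
    def _signal(T, params, sloped):
        Tm, dH, a_n, b_n, a_d, b_d = params
        # clip the exponent: K saturates numerically far from the transition
        K = np.exp(np.clip(-(dH / R_GAS_KJ) * (1.0 / T - 1.0 / Tm),
                           -500.0, 500.0))
        i_n = a_n + (b_n if sloped else 0.0) * (T - Tm)
        i_d = a_d + (b_d if sloped else 0.0) * (T - Tm)
        return (i_n + i_d * K) / (1.0 + K)

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).ravel()
        I = np.asarray(y, dtype=float).ravel()
        if len(T) != len(I):
            raise ValueError("temperature and signal lengths differ")
        if self.baseline_mode not in ("flat", "sloped"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        sloped = self.baseline_mode == "sloped"
        order = np.argsort(T)
        T, I = T[order], I[order]

        # initial guesses: Tm from the steepest finite-difference slope,
        # baselines from the trace ends, ΔHvh = 400 kJ/mol
        dIdT = np.gradient(I, T)
        tm0 = float(T[np.argmax(np.abs(dIdT))])
        tm0 = min(max(tm0, T[1]), T[-2])
        a_n0 = float(np.mean(I[:3]))
        a_d0 = float(np.mean(I[-3:]))
        span = max(abs(a_d0 - a_n0), 1e-12)

        rng = np.random.default_rng(self.seed)
        starts = [(tm0, 400.0)]
        for _ in range(max(0, self.n_restarts - 1)):
            starts.append((
                float(np.clip(tm0 + rng.normal(0, 5.0), T[1], T[-2])),
                float(400.0 * np.exp(rng.normal(0, 0.7))),
            ))

        scale = np.array([10.0, 100.0, span, span / 100.0, span, span / 100.0])
        best = None
        for tm_i, dh_i in starts:
            x0 = np.array([tm_i, dh_i, a_n0, 0.0, a_d0, 0.0])
            try:
                res = least_squares(
                    lambda p: self._signal(T, p, sloped) - I,
                    x0,
                    bounds=(
                        [T[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf],
                        [T[-1], 1e5, np.inf, np.inf, np.inf, np.inf],
                    ),
                    x_scale=scale,
                    method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimisation starts failed")

        p = best.x
        self.Tm_ = float(p[0])
        self.dHvh_ = float(p[1])
        self.dSvh_ = self.dHvh_ / self.Tm_
        self.baseline_native_ = (float(p[2]), float(p[3]) if sloped else 0.0)
        self.baseline_denatured_ = (float(p[4]), float(p[5]) if sloped else 0.0)
        self.residual_norm_ = float(np.sqrt(2 * best.cost))
        self._params_ = p
        self._sloped_ = sloped

        # acceptance: an interior Tm, positive enthalpy, and a transition
        # amplitude that clearly exceeds the residual scatter
        rmse = self.residual_norm_ / np.sqrt(len(T))
        amplitude = abs(p[4] - p[2])
        margin = 0.02 * (T[-1] - T[0])
        self.converged_ = bool(
            T[0] + margin < self.Tm_ < T[-1] - margin
            and self.dHvh_ > 0
            and amplitude > 5 * max(rmse, 1e-12)
        )
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).ravel()
        return self._signal(T, self._params_, self._sloped_)

    def unfolded_fraction(self, X):
        T = np.asarray(X, dtype=float).ravel()
        K = np.exp(-(self.dHvh_ / R_GAS_KJ) * (1.0 / T - 1.0 / self.Tm_))
        return K / (1.0 + K)


@dataclass
class TwoStateFitResult:
    Tm: float                         # K
    dHvh: float                       # kJ/mol
    dSvh: float                       # kJ/(mol K)
    baseline_native: tuple[float, float]
    baseline_denatured: tuple[float, float]
    residual_norm: float
    converged: bool

    @property
    def Tm_celsius(self) -> float:
        return k_to_c(self.Tm)


def fit_two_state(
    series: FluorescenceMeltSeries, baseline_mode: str = "flat",
) -> TwoStateFitResult:
    """Fit one melting trace; a trace with no resolvable transition comes
    back with ``converged=False`` and should not be interpreted."""
    model = TwoStateMeltModel(baseline_mode=baseline_mode)
    model.fit(series.temperatures, series.bcm)
    if not model.converged_:
        warnings.warn("two-state fit did not resolve a transition",
                      stacklevel=2)
    return TwoStateFitResult(
        Tm=model.Tm_,
        dHvh=model.dHvh_,
        dSvh=model.dSvh_,
        baseline_native=model.baseline_native_,
        baseline_denatured=model.baseline_denatured_,
        residual_norm=model.residual_norm_,
        converged=model.converged_,
    )


def dsvh(dHvh: float, Tm: float) -> float:
    """van't Hoff entropy at the midpoint: ΔSvh = ΔHvh/Tm (kJ/(mol·K))."""
    if Tm <= 0:
        raise ValueError("Tm must be positive")
    return dHvh / Tm


def summarize_replicates(
    fits: list[TwoStateFitResult],
) -> pd.DataFrame:
    """Mean and SEM of Tm (°C), ΔHvh and ΔSvh over replicate fits."""
    ok = [f for f in fits if f.converged]
    rows = {}
    for name, vals in (
        ("Tm_C", [k_to_c(f.Tm) for f in ok]),
        ("dHvh_kJ_mol", [f.dHvh for f in ok]),
        ("dSvh_kJ_molK", [f.dSvh for f in ok]),
    ):
        arr = np.asarray(vals)
        rows[name] = {
            "mean": arr.mean() if len(arr) else np.nan,
            "sem": (arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan,
            "n": len(arr),
        }
    return pd.DataFrame(rows).T
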