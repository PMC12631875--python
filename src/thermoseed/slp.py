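"""Specific loss power (SLP) estimation and the self-regulating SLP(T) curve.

SLP is the heat released per unit mass of magnetic material in an alternating
field.  It is estimated calorimetrically from the initial slope of a heating
curve,

    SLP = c_p,disp * (dT/dt)_0 * m_disp / m_MNP        [W/g],

and its temperature dependence — the Curie-limited self-regulation that makes
the seeds saturate near the therapeutic band — is modelled as a Gaussian plus
offset,

    SLP(T) = a * exp(-((T - b)/c)^2) + d,

with a peak at T = b and a high-temperature floor d.  The published fit for
the composite seed is a = 0.972 W/g, b = 32.002 degC, c = 19.012 degC,
d = 0.782 W/g.

The Gaussian fit is exposed both as a plain function (:func:`fit_slp_gaussian`)
and as a small model/results pair (:class:`SLPCurveModel` /
:class:`SLPCurveFit`) carrying parameter standard errors and an R^2 summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HeatingCurve",
    "SLPGaussianParams",
    "SLPSample",
    "DEFAULT_SLP_PARAMS",
    "slp_from_heating_curve",
    "eval_slp",
    "fit_slp_gaussian",
    "SLPCurveModel",
    "SLPCurveFit",
    "read_heating_curve_csv",
    "read_slp_samples_csv",
    "write_slp_samples_csv",
]


@dataclass(frozen=True)
class HeatingCurve:
    """A calorimetric temperature-time record of a magnetic dispersion.

    ``c_p_dispersion`` in J/(g.degC), masses in grams, times in seconds.
    """

    times: np.ndarray
    temperatures: np.ndarray
    c_p_dispersion: float
    mass_dispersion: float
    mass_mnp: float
    initial_temperature: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", T)
        if t.size < 5:
            raise ValueError("heating curve needs at least 5 samples")
        if t.size != T.size:
            raise ValueError("times and temperatures must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.mass_mnp <= 0 or self.mass_dispersion <= 0:
            raise ValueError("masses must be > 0")
        if self.c_p_dispersion <= 0:
            raise ValueError("c_p_dispersion must be > 0")
        if self.initial_temperature is None:
            object.__setattr__(self, "initial_temperature", float(T[0]))


@dataclass(frozen=True)
class SLPGaussianParams:
    """Constants of the Gaussian-plus-offset self-regulating SLP curve."""

    a: float  # peak amplitude above floor, W/g
    b: float  # peak temperature, degC
    c: float  # Gaussian width, degC
    d: float  # high-temperature floor, W/g

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("width c must be > 0")
        if self.a < 0 or self.d < 0:
            raise ValueError("a and d must be >= 0")


#: Published fit constants for the composite seed (W/g, degC).
DEFAULT_SLP_PARAMS = SLPGaussianParams(a=0.972, b=32.002, c=19.012, d=0.782)


@dataclass(frozen=True)
class SLPSample:
    """One SLP measurement tagged with its (initial) temperature."""

    temperature: float
    slp: float
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.slp < 0:
            raise ValueError("SLP must be >= 0")


def slp_from_heating_curve(
    curve: HeatingCurve, slope_window: int | None = None
) -> SLPSample:
    """Estimate SLP from the initial slope of a heating curve.

    The slope dT/dt is taken by least squares over the first ``slope_window``
    samples (default: all samples within the first 10 s, when heat loss is
    negligible).  A negative estimated slope is clamped to SLP = 0 with a
    warning.
    """
    n = curve.times.size
    if slope_window is None:
        slope_window = max(2, int(np.searchsorted(curve.times, curve.times[0] + 10.0)))
        slope_window = min(slope_window, n)
    if slope_window < 2 or slope_window > n:
        raise ValueError(f"slope_window must be in [2, {n}], got {slope_window}")
    t = curve.times[:slope_window]
    T = curve.temperatures[:slope_window]
    slope = np.polyfit(t, T, 1)[0]
    if slope < 0:
        warnings.warn(
            "negative initial slope; SLP clamped to 0", RuntimeWarning, stacklevel=2
        )
        slope = 0.0
    slp = curve.c_p_dispersion * slope * curve.mass_dispersion / curve.mass_mnp
    return SLPSample(temperature=float(curve.initial_temperature), slp=float(slp))


def eval_slp(params: SLPGaussianParams, T):
    """Evaluate the self-regulating SLP curve at temperature(s) T (degC), W/g."""
    T = np.asarray(T, dtype=float)
    return (params.a * np.exp(-(((T - params.b) / params.c) ** 2)) + params.d)[()]


def _gauss(T, a, b, c, d):
    return a * np.exp(-(((T - b) / c) ** 2)) + d


def _default_guess(temps: np.ndarray, slps: np.ndarray) -> SLPGaussianParams:
    spread = max(slps.max() - slps.min(), 1e-6)
    width = max(0.5 * (temps.max() - temps.min()), 1e-3)
    return SLPGaussianParams(
        a=spread, b=float(temps[np.argmax(slps)]), c=width, d=float(slps.min())
    )


def fit_slp_gaussian(
    samples: Sequence[SLPSample],
    initial_guess: SLPGaussianParams | None = None,
) -> tuple[SLPGaussianParams, float]:
    """Nonlinear least-squares fit of the Gaussian-plus-offset SLP curve.

    Returns the fitted parameters and the coefficient of determination
    R^2 = 1 - SS_res / SS_tot over the fitted samples.  Requires samples at
    >= 4 distinct temperatures.  Deterministic for identical inputs and guess.
    """
    fit = SLPCurveModel.from_samples(samples).fit(initial_guess=initial_guess)
    return fit.params, fit.rsquared


class SLPCurveModel:
    """Self-regulating SLP(T) curve model bound to measured samples.

    Construct from :class:`SLPSample` objects or a DataFrame with columns
    ``temp_C`` and ``slp_W_per_g``; ``fit()`` returns an :class:`SLPCurveFit`.
    """

    def __init__(self, temperatures, slps) -> None:
        self.temperatures = np.asarray(temperatures, dtype=float)
        self.slps = np.asarray(slps, dtype=float)
        if self.temperatures.size != self.slps.size:
            raise ValueError("temperatures and slps must have equal length")
        if np.unique(self.temperatures).size < 4:
            raise ValueError("need samples at >= 4 distinct temperatures")

    @classmethod
    def from_samples(cls, samples: Sequence[SLPSample]) -> "SLPCurveModel":
        if len(samples) < 4:
            raise ValueError("need >= 4 samples")
        return cls([s.temperature for s in samples], [s.slp for s in samples])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SLPCurveModel":
        return cls(df["temp_C"].to_numpy(), df["slp_W_per_g"].to_numpy())

    def fit(
        self,
        initial_guess: SLPGaussianParams | None = None,
        max_iterations: int = 10000,
    ) -> "SLPCurveFit":
        guess = initial_guess or _default_guess(self.temperatures, self.slps)
        p0 = [guess.a, guess.b, guess.c, guess.d]
        try:
            popt, pcov = curve_fit(
                _gauss,
                self.temperatures,
                self.slps,
                p0=p0,
                bounds=([0.0, -np.inf, 1e-9, 0.0], np.inf),
                maxfev=max_iterations,
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"SLP Gaussian fit did not converge from guess {p0}: {err}"
            ) from err
        params = SLPGaussianParams(*[float(v) for v in popt])
        resid = self.slps - _gauss(self.temperatures, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((self.slps - self.slps.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        bse = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        degenerate = ss_tot == 0.0 or params.a < 1e-9 * max(params.d, 1.0)
        return SLPCurveFit(
            model=self,
            params=params,
            bse=bse,
            rsquared=r2,
            ss_res=ss_res,
            degenerate=degenerate,
        )


@dataclass(frozen=True)
class SLPCurveFit:
    """Results of an SLP curve fit: estimates, standard errors, diagnostics."""

    model: SLPCurveModel
    params: SLPGaussianParams
    bse: np.ndarray
    rsquared: float
    ss_res: float
    degenerate: bool = False

    def predict(self, T):
        return eval_slp(self.params, T)

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Self-regulating SLP(T) Gaussian fit",
            "===================================",
            f"observations: {self.model.temperatures.size}",
            f"R^2:          {self.rsquared:.4f}",
            "",
            "param   estimate      std err   unit",
            f"a     {p.a:10.4f} {se[0]:12.4f}   W/g",
            f"b     {p.b:10.4f} {se[1]:12.4f}   degC",
            f"c     {p.c:10.4f} {se[2]:12.4f}   degC",
            f"d     {p.d:10.4f} {se[3]:12.4f}   W/g",
        ]
        if self.degenerate:
            lines.append("warning: degenerate (flat) fit — amplitude ~ 0")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV dialects

def read_heating_curve_csv(
    path, c_p_dispersion: float, mass_dispersion: float, mass_mnp: float
) -> HeatingCurve:
    """Read a (time_s, temp_C) CSV into a :class:`HeatingCurve`."""
    df = pd.read_csv(path)
    return HeatingCurve(
        times=df["time_s"].to_numpy(),
        temperatures=df["temp_C"].to_numpy(),
        c_p_dispersion=c_p_dispersion,
        mass_dispersion=mass_dispersion,
        mass_mnp=mass_mnp,
    )


def read_slp_samples_csv(path) -> list[SLPSample]:
    """Read a (temp_C, slp_W_per_g) CSV into SLP samples."""
    df = pd.read_csv(path)
    return [
        SLPSample(temperature=float(r.temp_C), slp=float(r.slp_W_per_g))
        for r in df.itertuples()
    ]


def write_slp_samples_csv(samples: Sequence[SLPSample], path) -> None:
    pd.DataFrame(
        {
            "temp_C": [s.temperature for s in samples],
            "slp_W_per_g": [s.slp for s in samples],
        }
    ).to_csv(path, index=False)
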