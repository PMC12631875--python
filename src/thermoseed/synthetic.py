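"""Synthetic calorimetry data with known ground truth.

Emulates the hydrogel calorimetry setup used to characterize the seeds: a
dispersion of known mass and heat capacity heated in an alternating field,
recorded by a fiber-optic thermometer.  The heating curve follows a
saturating exponential

    T(t) = T0 + dT_eq * (1 - exp(-t / tau)) + noise,

whose initial slope dT_eq / tau is set exactly to the slope implied by the
requested true SLP, so the generator doubles as an oracle for the SLP
estimator.  Noise is i.i.d. Gaussian on each temperature reading (default
sd 0.1 degC, matching the thermometer-spread control of the measurement
protocol); tau defaults to 300 s (Newtonian heat loss to the bath).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .slp import HeatingCurve, SLPGaussianParams, SLPSample, eval_slp

__all__ = ["CurveGenSpec", "gen_heating_curve", "gen_slp_samples"]


@dataclass(frozen=True)
class CurveGenSpec:
    """Specification of one synthetic calorimetric heating curve.

    ``slp_true`` in W/g; masses in g; ``c_p_dispersion`` in J/(g.degC);
    ``ambient_loss_time_constant`` (tau) and times in seconds.
    """

    slp_true: float
    c_p_dispersion: float = 2.30
    mass_dispersion: float = 2.0
    mass_mnp: float = 0.01
    ambient_loss_time_constant: float = 300.0
    initial_temperature: float = 25.0
    noise_sd: float = 0.1
    rng_seed: int = 0
    duration: float = 180.0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_dispersion <= 0 or self.mass_mnp <= 0:
            raise ValueError("masses must be > 0")
        if self.ambient_loss_time_constant <= 0:
            raise ValueError("time constant must be > 0")
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValueError("duration and sample_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slp_true < 0:
            raise ValueError("slp_true must be >= 0")


def heating_model(spec: CurveGenSpec, t):
    """Noise-free closed-form curve T(t) for ``spec`` (the generator oracle)."""
    slope0 = (
        spec.slp_true
        * spec.mass_mnp
        / (spec.c_p_dispersion * spec.mass_dispersion)
    )
    tau = spec.ambient_loss_time_constant
    dT_eq = slope0 * tau
    return spec.initial_temperature + dT_eq * (1.0 - np.exp(-np.asarray(t) / tau))


def gen_heating_curve(spec: CurveGenSpec) -> HeatingCurve:
    """Generate a noisy saturating heating curve with known true SLP.

    Pure function of (spec, rng_seed): the same spec reproduces the same
    curve bit-for-bit.
    """
    t = np.arange(0.0, spec.duration + 0.5 * spec.sample_interval, spec.sample_interval)
    T = heating_model(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        T = T + rng.normal(0.0, spec.noise_sd, size=t.size)
    return HeatingCurve(
        times=t,
        temperatures=T,
        c_p_dispersion=spec.c_p_dispersion,
        mass_dispersion=spec.mass_dispersion,
        mass_mnp=spec.mass_mnp,
        initial_temperature=spec.initial_temperature,
    )


def gen_slp_samples(
    params: SLPGaussianParams,
    temperatures: Sequence[float],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> list[SLPSample]:
    """Draw SLP-vs-temperature samples from the Gaussian model plus noise.

    Negative noisy draws are clamped at zero (SLP is nonnegative by
    definition).  Seeded and reproducible; an empty temperature list yields
    an empty sample list.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    temps = np.asarray(list(temperatures), dtype=float)
    if temps.size == 0:
        return []
    values = np.atleast_1d(eval_slp(params, temps)).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        values = values + rng.normal(0.0, noise_sd, size=temps.size)
    values = np.maximum(values, 0.0)
    return [
        SLPSample(temperature=float(T), slp=float(v))
        for T, v in zip(temps, values)
    ]
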