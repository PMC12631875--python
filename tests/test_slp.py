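"""SLP estimation from heating curves and the self-regulating Gaussian fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoseed.slp import (
    DEFAULT_SLP_PARAMS,
    HeatingCurve,
    SLPCurveModel,
    SLPGaussianParams,
    SLPSample,
    eval_slp,
    fit_slp_gaussian,
    slp_from_heating_curve,
)
from thermoseed.synthetic import CurveGenSpec, gen_heating_curve, gen_slp_samples


def _curve(times, temps, cp=2.30, m_disp=2.0, m_mnp=0.01):
    return HeatingCurve(
        times=np.asarray(times, float),
        temperatures=np.asarray(temps, float),
        c_p_dispersion=cp,
        mass_dispersion=m_disp,
        mass_mnp=m_mnp,
    )


class TestSlpFromHeatingCurve:
    def test_flat_curve_gives_zero(self):
        t = np.arange(0.0, 60.0, 1.0)
        s = slp_from_heating_curve(_curve(t, np.full_like(t, 25.0)))
        assert s.slp == 0.0

    def test_linear_curve_exact(self):
        """0.05 degC/s at c_p = 2.30 J/(g degC) and mass ratio 200 -> 23 W/g."""
        t = np.arange(0.0, 60.0, 1.0)
        s = slp_from_heating_curve(_curve(t, 25.0 + 0.05 * t))
        assert s.slp == pytest.approx(23.0, rel=1e-9)
        assert s.temperature == 25.0

    def test_saturating_curve_recovery_within_5pct(self):
        """Slope window well inside the loss time constant recovers the
        generator's true SLP."""
        spec = CurveGenSpec(slp_true=10.0, noise_sd=0.0,
                            ambient_loss_time_constant=300.0,
                            sample_interval=0.5)
        curve = gen_heating_curve(spec)
        s = slp_from_heating_curve(curve, slope_window=20)  # first 10 s
        assert s.slp == pytest.approx(10.0, rel=0.05)

    def test_offset_invariance(self):
        t = np.arange(0.0, 30.0, 1.0)
        temps = 25.0 + 0.03 * t + 0.01 * np.sin(t)
        a = slp_from_heating_curve(_curve(t, temps), slope_window=10)
        b = slp_from_heating_curve(_curve(t, temps + 7.5), slope_window=10)
        assert a.slp == pytest.approx(b.slp, rel=1e-12)

    def test_negative_slope_clamped_with_warning(self):
        t = np.arange(0.0, 30.0, 1.0)
        with pytest.warns(RuntimeWarning):
            s = slp_from_heating_curve(_curve(t, 40.0 - 0.02 * t))
        assert s.slp == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            _curve([0, 1, 2, 3], [25, 25, 25, 25])

    def test_bad_slope_window_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            slp_from_heating_curve(_curve(t, 25.0 + 0.1 * t), slope_window=1)


class TestEvalSlp:
    def test_peak_value(self):
        assert eval_slp(DEFAULT_SLP_PARAMS, 32.002) == pytest.approx(1.754)

    def test_asymptote(self):
        assert eval_slp(DEFAULT_SLP_PARAMS, 500.0) == pytest.approx(0.782, abs=1e-6)

    def test_at_50C(self):
        assert eval_slp(DEFAULT_SLP_PARAMS, 50.0) == pytest.approx(1.179, abs=2e-3)

    @given(dT=st.floats(0.1, 40.0))
    @settings(max_examples=40, deadline=None)
    def test_symmetry_and_decrease_above_peak(self, dT):
        p = DEFAULT_SLP_PARAMS
        left = eval_slp(p, p.b - dT)
        right = eval_slp(p, p.b + dT)
        assert left == pytest.approx(right, rel=1e-12)
        assert eval_slp(p, p.b + dT) < eval_slp(p, p.b + 0.5 * dT) < eval_slp(p, p.b)


class TestGaussianFit:
    def test_noiseless_round_trip(self):
        temps = np.arange(25.0, 80.0, 5.0)
        samples = gen_slp_samples(DEFAULT_SLP_PARAMS, temps, noise_sd=0.0)
        params, r2 = fit_slp_gaussian(samples)
        for got, true in zip(
            (params.a, params.b, params.c, params.d),
            (DEFAULT_SLP_PARAMS.a, DEFAULT_SLP_PARAMS.b,
             DEFAULT_SLP_PARAMS.c, DEFAULT_SLP_PARAMS.d),
        ):
            assert got == pytest.approx(true, rel=1e-3)
        assert r2 >= 0.9999

    def test_perturbed_initial_guess_same_optimum(self):
        temps = np.arange(25.0, 80.0, 5.0)
        samples = gen_slp_samples(DEFAULT_SLP_PARAMS, temps, noise_sd=0.0)
        p = DEFAULT_SLP_PARAMS
        guess = SLPGaussianParams(a=p.a * 1.5, b=p.b * 0.5, c=p.c * 1.5, d=p.d * 0.5)
        params, _ = fit_slp_gaussian(samples, initial_guess=guess)
        assert params.a == pytest.approx(p.a, rel=1e-3)
        assert params.b == pytest.approx(p.b, rel=1e-3)
        assert params.c == pytest.approx(p.c, rel=1e-3)
        assert params.d == pytest.approx(p.d, rel=1e-3)

    def test_flat_data_degenerate_flagged(self):
        samples = [SLPSample(temperature=t, slp=0.9) for t in (25, 35, 45, 55, 65)]
        fit = SLPCurveModel.from_samples(samples).fit()
        assert fit.degenerate
        assert eval_slp(fit.params, 40.0) == pytest.approx(0.9, abs=1e-6)

    def test_too_few_distinct_temperatures_rejected(self):
        samples = [SLPSample(temperature=t, slp=1.0) for t in (25, 25, 30, 30, 35)]
        with pytest.raises(ValueError):
            SLPCurveModel.from_samples(samples)

    def test_noisy_recovery_within_5pct(self):
        """Four replicates at each of 25..75 degC with 0.02 W/g noise."""
        temps = np.repeat(np.arange(25.0, 80.0, 5.0), 4)
        samples = gen_slp_samples(DEFAULT_SLP_PARAMS, temps, noise_sd=0.02, rng_seed=0)
        params, r2 = fit_slp_gaussian(samples)
        p = DEFAULT_SLP_PARAMS
        assert params.a == pytest.approx(p.a, rel=0.05)
        assert params.b == pytest.approx(p.b, rel=0.05)
        assert params.c == pytest.approx(p.c, rel=0.05)
        assert params.d == pytest.approx(p.d, rel=0.05)

    def test_summary_mentions_fit_quality(self):
        temps = np.arange(25.0, 80.0, 5.0)
        fit = SLPCurveModel.from_samples(
            gen_slp_samples(DEFAULT_SLP_PARAMS, temps)
        ).fit()
        text = fit.summary()
        assert "R^2" in text and "W/g" in text
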