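"""Bridge conversion, low-pass filtering and the thermal self-elimination flow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canticomp as cc
from canticomp.compensation import lowpass, residual_sensitivity
from canticomp.errors import ConfigError, OutOfRangeError
from canticomp.sensor_sim import SensorScenario, SineDrift


# --- bridge -----------------------------------------------------------------


def test_bridge_conversion_worked_example(unit_bridge):
    # dR = 1.08 Ohm on a 0.3 V / 2700 Ohm quarter bridge, unity gain
    v = cc.resistance_to_voltage(1.08, unit_bridge)
    assert v == pytest.approx(-3.0e-5, rel=1e-12)


def test_bridge_zero_maps_to_zero(unit_bridge):
    assert cc.resistance_to_voltage(0.0, unit_bridge) == 0.0
    assert cc.voltage_to_resistance(0.0, unit_bridge) == 0.0


@pytest.mark.parametrize("x", [-5.0, 0.0, 7.3])
def test_bridge_inverse_pair(x, unit_bridge):
    v = cc.resistance_to_voltage(x, unit_bridge)
    assert cc.voltage_to_resistance(v, unit_bridge) == pytest.approx(x, abs=1e-12)


def test_bridge_inverse_example(unit_bridge):
    assert cc.voltage_to_resistance(-3.0e-5, unit_bridge) == pytest.approx(1.08, abs=1e-12)


@given(dr=st.floats(-100.0, 100.0), scale=st.floats(0.1, 10.0))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_bridge_linearity_property(dr, scale):
    bridge = cc.BridgeConfig(supply_v=0.3, balance_r=2700.0, gain=1.0)
    one = cc.resistance_to_voltage(dr, bridge)
    two = cc.resistance_to_voltage(scale * dr, bridge)
    assert two == pytest.approx(scale * one, rel=1e-12, abs=1e-300)


def test_bridge_config_validation():
    with pytest.raises(ConfigError):
        cc.BridgeConfig(supply_v=0.0)
    with pytest.raises(ConfigError):
        cc.BridgeConfig(balance_r=-1.0)
    with pytest.raises(ConfigError):
        cc.BridgeConfig(gain=0.5)
    with pytest.raises(ConfigError):
        cc.BridgeConfig(sign=2)


def test_unresolved_balance_rejected():
    with pytest.raises(ConfigError, match="balance_r"):
        cc.resistance_to_voltage(1.0, cc.BridgeConfig())


# --- low-pass ---------------------------------------------------------------


def test_lowpass_preserves_constant():
    cfg = cc.FilterConfig(cutoff_hz=0.1, sample_dt=1.0, order=1)
    x = np.full(100, 3.7)
    assert np.array_equal(lowpass(x, cfg), x)


def test_lowpass_step_response_reaches_tau_level():
    # order-1 RC: ~63 % of a unit step after RC = 1/(2 pi f_c) seconds
    cfg = cc.FilterConfig(cutoff_hz=0.1, sample_dt=0.1, order=1)
    n = 500
    x = np.ones(n)
    x[0] = 0.0  # start from rest at the first sample
    y = lowpass(x, cfg)
    rc = 1.0 / (2.0 * np.pi * cfg.cutoff_hz)
    i_tau = int(np.ceil(rc / cfg.sample_dt))
    assert np.all(np.diff(y) >= -1e-15)  # monotone rise
    assert y[i_tau] >= 0.63
    assert y[-1] == pytest.approx(1.0, abs=1e-6)


def test_lowpass_reduces_white_noise_variance():
    rng = np.random.default_rng(11)
    x = rng.normal(0.0, 1.0, 5000)
    cfg = cc.FilterConfig(cutoff_hz=0.05, sample_dt=1.0, order=1)
    y = lowpass(x, cfg)
    assert np.var(y) < np.var(x)


def test_lowpass_higher_order_keeps_dc_gain():
    cfg = cc.FilterConfig(cutoff_hz=0.1, sample_dt=1.0, order=3)
    x = np.full(200, -1.25)
    assert np.array_equal(lowpass(x, cfg), x)


def test_lowpass_nyquist_violation_rejected():
    with pytest.raises(ConfigError, match="Nyquist"):
        cc.FilterConfig(cutoff_hz=0.6, sample_dt=1.0)


# --- residual sensitivity ---------------------------------------------------


def test_constant_output_has_zero_slope():
    t = np.linspace(10.0, 40.0, 50)
    assert residual_sensitivity(np.full(50, 2e-3), t) == pytest.approx(0.0, abs=1e-12)


def test_exact_line_slope_recovered():
    t = np.linspace(13.6, 40.7, 200)
    v = 25.6e-6 * (t - t[0])
    assert residual_sensitivity(v, t) == pytest.approx(25.6, rel=1e-9)


def test_slope_reported_pre_amplifier():
    t = np.linspace(20.0, 40.0, 100)
    v = 1000.0 * 2.0e-6 * (t - 30.0)
    assert residual_sensitivity(v, t, gain=1000.0) == pytest.approx(2.0, rel=1e-9)


def test_noisy_line_slope_within_three_standard_errors():
    rng = np.random.default_rng(5)
    t = np.linspace(0.0, 30.0, 1000)
    true_slope = 4.2e-6  # V/degC
    sigma = 1e-5
    v = true_slope * t + rng.normal(0.0, sigma, t.size)
    est = residual_sensitivity(v, t)
    se = sigma / np.sqrt(np.sum((t - t.mean()) ** 2)) * 1e6
    assert abs(est - true_slope * 1e6) <= 3.0 * se


def test_zero_span_rejected():
    with pytest.raises(ValueError, match="span"):
        residual_sensitivity(np.arange(5.0), np.full(5, 25.0))


# --- compensation flow ------------------------------------------------------


def _noiseless_traces(sine_scenario_factory, bridge, events=()):
    scenario = sine_scenario_factory(noise=0.0, quant=0.0, events=events)
    traces = cc.simulate(scenario, bridge=bridge)
    return scenario, traces


def test_exact_cancellation_with_perfect_model(sine_scenario_factory, oc_curve,
                                               mcl_curve, bridge):
    """The method's defining property: a purely thermal signal cancels to < 1 nV."""
    _, traces = _noiseless_traces(sine_scenario_factory, bridge)
    result = cc.compensate_stream(traces.r_oc, traces.v_mcl, oc_curve, mcl_curve,
                                  bridge, None, time=traces.time)
    assert np.max(np.abs(result.v_out)) < 1e-9


def test_binding_transparency(sine_scenario_factory, oc_curve, mcl_curve, bridge):
    """Adding b(t) to V_MCL moves V_Out by exactly b(t)."""
    _, traces = _noiseless_traces(sine_scenario_factory, bridge)
    b = 5e-5 * np.sin(np.linspace(0.0, 3.0, traces.time.size))
    base = cc.compensate_stream(traces.r_oc, traces.v_mcl, oc_curve, mcl_curve,
                                bridge, None, time=traces.time)
    shifted = cc.compensate_stream(traces.r_oc, traces.v_mcl + b, oc_curve, mcl_curve,
                                   bridge, None, time=traces.time)
    assert np.allclose(shifted.v_out - base.v_out, b, rtol=0.0, atol=1e-15)


def test_constant_binding_offset_passes_through(sine_scenario_factory, oc_curve,
                                                mcl_curve, bridge):
    _, traces = _noiseless_traces(sine_scenario_factory, bridge)
    v_b = -4.3e-5
    result = cc.compensate_stream(traces.r_oc, traces.v_mcl + v_b, oc_curve, mcl_curve,
                                  bridge, None, time=traces.time)
    assert np.allclose(result.v_out, v_b, rtol=0.0, atol=1e-9)


def test_gain_factoring(sine_scenario_factory, oc_curve, mcl_curve):
    """Pipeline at gain g, divided by g, equals the unit-gain pipeline."""
    hi = cc.BridgeConfig(supply_v=0.3, gain=1000.0)
    lo = cc.BridgeConfig(supply_v=0.3, gain=1.0)
    scenario = cc.SensorScenario(
        duration=600.0, sample_dt=1.0,
        temperature_path=SineDrift(mean=40.0, amplitude=5.0, period=300.0),
        resistance_noise_sd=0.2, quantization_step=0.1, seed=3, name="gain",
    )
    tr_hi = cc.simulate(scenario, bridge=hi)
    tr_lo = cc.simulate(scenario, bridge=lo)
    res_hi = cc.compensate_stream(tr_hi.r_oc, tr_hi.v_mcl, oc_curve, mcl_curve, hi, None)
    res_lo = cc.compensate_stream(tr_lo.r_oc, tr_lo.v_mcl, oc_curve, mcl_curve, lo, None)
    assert np.allclose(res_hi.v_out / 1000.0, res_lo.v_out, rtol=1e-12, atol=1e-300)
    assert res_hi.residual_sensitivity == pytest.approx(res_lo.residual_sensitivity,
                                                        rel=1e-9)


def test_filter_and_constant_offset_commute_at_dc(sine_scenario_factory, oc_curve,
                                                  mcl_curve, bridge):
    _, traces = _noiseless_traces(sine_scenario_factory, bridge)
    filt = cc.FilterConfig(cutoff_hz=0.1, sample_dt=1.0)
    offset = 2.5e-4
    before = cc.compensate_stream(traces.r_oc, traces.v_mcl + offset, oc_curve,
                                  mcl_curve, bridge, filt, time=traces.time)
    after = cc.compensate_stream(traces.r_oc, traces.v_mcl, oc_curve, mcl_curve,
                                 bridge, filt, time=traces.time)
    assert np.allclose(before.v_out, after.v_out + offset, rtol=0.0, atol=1e-12)


def test_length_mismatch_rejected(oc_curve, mcl_curve, bridge):
    with pytest.raises(ValueError, match="aligned"):
        cc.compensate_stream(np.full(5, 2720.0), np.zeros(4), oc_curve, mcl_curve, bridge)


def test_impossible_resistance_propagates_sample_index(oc_curve, mcl_curve, bridge):
    # second sample falls below the parabola extremum: no real preimage
    r_oc = np.array([2721.3, 2600.0, 2721.3, 2721.4])
    with pytest.raises(OutOfRangeError, match="sample 1"):
        cc.compensate_stream(r_oc, np.zeros(4), oc_curve, mcl_curve, bridge)


def test_residual_sensitivity_prefers_reference_temperature(oc_curve, mcl_curve, bridge):
    scenario = SensorScenario(
        duration=900.0, sample_dt=1.0,
        temperature_path=SineDrift(mean=45.0, amplitude=10.0, period=900.0),
        resistance_noise_sd=0.5, quantization_step=0.1, seed=12, name="ref",
    )
    traces = cc.simulate(scenario, bridge=bridge)
    res = cc.compensate_stream(traces.r_oc, traces.v_mcl, oc_curve, mcl_curve, bridge,
                               None, time=traces.time, t_ref=traces.t_true)
    # against the clean reference the residual slope is small; against the
    # noisy inferred temperature it is biased upward by errors-in-variables
    res_sys = cc.compensate_stream(traces.r_oc, traces.v_mcl, oc_curve, mcl_curve,
                                   bridge, None, time=traces.time)
    assert abs(res.residual_sensitivity) < abs(res_sys.residual_sensitivity)
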