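import logging

import pytest

import canticomp as cc


@pytest.fixture(autouse=True)
def _quiet_extrapolation_logs():
    # the noisy-thermometer scenarios legitimately extrapolate; keep test
    # output readable without disabling the logging contract itself
    logging.getLogger("canticomp").setLevel(logging.ERROR)
    yield
    logging.getLogger("canticomp").setLevel(logging.NOTSET)


@pytest.fixture
def oc_curve():
    return cc.default_onchip_curve()


@pytest.fixture
def mcl_curve():
    return cc.default_mcl_curve()


@pytest.fixture
def bridge():
    return cc.BridgeConfig(supply_v=0.3, gain=1000.0)


@pytest.fixture
def unit_bridge():
    """Pre-amplifier view of the bridge from the worked conversion example."""
    return cc.BridgeConfig(supply_v=0.3, balance_r=2700.0, gain=1.0)


@pytest.fixture
def scenarios():
    return cc.default_scenarios()


def make_sine_scenario(seed=0, noise=0.0, quant=0.0, events=(), duration=1200.0,
                       mean=35.0, amplitude=10.0, period=600.0):
    """A within-band thermal path for exactness tests."""
    from canticomp.sensor_sim import SensorScenario, SineDrift

    return SensorScenario(
        duration=duration, sample_dt=1.0,
        temperature_path=SineDrift(mean=mean, amplitude=amplitude, period=period),
        events=tuple(events), resistance_noise_sd=noise, quantization_step=quant,
        seed=seed, name="test_sine",
    )


@pytest.fixture
def sine_scenario_factory():
    return make_sine_scenario
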