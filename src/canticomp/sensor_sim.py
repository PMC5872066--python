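"""Synthetic raw-trace generator for the cantilever biosensor.

The simulator uses the device's empirical quadratic R(T) laws as ground
truth (no physical multimorph model is attempted; the layer stack is carried
as metadata only).  For a prescribed temperature trajectory and a set of
binding events it produces the observables the instrument records:

* the on-chip thermometer resistance R_OC (meter-quantized, noisy),
* the cantilever resistance R_MCL (thermal law + stress-induced change,
  quantized, noisy),
* the amplified bridge voltage V_MCL,

together with the ground-truth temperature and surface-stress series, so the
whole compensation pipeline can be exercised and verified without hardware.

Binding events follow first-order (Langmuir-like) saturation kinetics:
sigma(t) = sigma_max * (1 - exp(-(t - t_on)/tau_on)) for t >= t_on.  Surface
stress couples to the cantilever resistance through the transduction
constant ``k_sigma`` (Ohm per N/m) -- a device property the data sheet does
not pin down; its default is a documented placeholder giving a few-Ohm
change for typical protein-binding stresses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .calibration import CalibrationCurve, default_mcl_curve, default_onchip_curve, evaluate
from .compensation import BridgeConfig, resistance_to_voltage
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Default stress-to-resistance transduction (Ohm per N/m).  Placeholder:
#: chosen so a -3.1 N/m binding event moves the bridge by ~40 uV
#: (pre-amplifier) on a 0.3 V supply, the order seen in CRP detection runs.
K_SIGMA_DEFAULT = 0.5

#: Meter quantization step (Ohm) of the resistance readout.
METER_STEP = 0.1


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the cantilever stack."""

    material: str
    thickness_nm: float

    def __post_init__(self) -> None:
        if self.thickness_nm <= 0:
            raise ValueError("layer thickness must be > 0")


@dataclass(frozen=True)
class CantileverGeometry:
    """Planar dimensions and layer stack (top to bottom) of the beam."""

    length_um: float
    width_um: float
    layers: tuple[LayerSpec, ...]


#: Reference five-layer beam: 200 x 150 um, 1.265 um total stack.
REFERENCE_GEOMETRY = CantileverGeometry(
    length_um=200.0,
    width_um=150.0,
    layers=(
        LayerSpec("gold", 35.0),
        LayerSpec("silicon nitride", 350.0),
        LayerSpec("polysilicon", 180.0),
        LayerSpec("silicon nitride", 600.0),
        LayerSpec("silicon oxide", 100.0),
    ),
)


def stack_thickness(geom: CantileverGeometry) -> float:
    """Total stack thickness in micrometres."""
    if not geom.layers:
        raise ValueError("geometry has no layers")
    return sum(layer.thickness_nm for layer in geom.layers) / 1000.0


@dataclass(frozen=True)
class BindingEvent:
    """A single binding step: exponential approach to ``sigma_max``.

    sigma_max is in N/m; negative = compressive surface stress (the beam
    bends away from the functionalized side).
    """

    t_on: float
    sigma_max: float
    tau_on: float

    def __post_init__(self) -> None:
        if self.tau_on <= 0:
            raise ValueError("tau_on must be > 0")

    def stress(self, time: np.ndarray) -> np.ndarray:
        t = np.asarray(time, dtype=float)
        s = np.zeros_like(t)
        on = t >= self.t_on
        s[on] = self.sigma_max * (1.0 - np.exp(-(t[on] - self.t_on) / self.tau_on))
        return s


# --- temperature profiles ---------------------------------------------------


@dataclass(frozen=True)
class ConstantTemperature:
    t_c: float

    def __call__(self, time):
        return np.full_like(np.asarray(time, dtype=float), self.t_c)

    def to_dict(self) -> dict:
        return {"kind": "constant", "t_C": self.t_c}


@dataclass(frozen=True)
class LinearRamp:
    """Linear drift from ``t_start`` at time 0 to ``t_end`` at ``duration``."""

    t_start: float
    t_end: float
    duration: float

    @property
    def span(self) -> float:
        return abs(self.t_end - self.t_start)

    def __call__(self, time):
        t = np.asarray(time, dtype=float)
        frac = np.clip(t / self.duration, 0.0, 1.0)
        return self.t_start + (self.t_end - self.t_start) * frac

    def to_dict(self) -> dict:
        return {"kind": "linear", "t_start_C": self.t_start,
                "t_end_C": self.t_end, "duration_s": self.duration}


@dataclass(frozen=True)
class SineDrift:
    """Slow sinusoidal ambient drift around ``mean`` (amplitude in degC)."""

    mean: float
    amplitude: float
    period: float

    def __call__(self, time):
        t = np.asarray(time, dtype=float)
        return self.mean + self.amplitude * np.sin(2.0 * np.pi * t / self.period)

    def to_dict(self) -> dict:
        return {"kind": "sine", "mean_C": self.mean,
                "amplitude_C": self.amplitude, "period_s": self.period}


def profile_from_dict(d: dict):
    """Inverse of the profiles' ``to_dict`` (used by scenario JSON files)."""
    kind = d.get("kind")
    if kind == "constant":
        return ConstantTemperature(float(d["t_C"]))
    if kind == "linear":
        return LinearRamp(float(d["t_start_C"]), float(d["t_end_C"]), float(d["duration_s"]))
    if kind == "sine":
        return SineDrift(float(d["mean_C"]), float(d["amplitude_C"]), float(d["period_s"]))
    raise ConfigError(f"unknown temperature profile kind {kind!r}")


@dataclass
class SensorScenario:
    """Everything needed to generate one reproducible raw trace."""

    duration: float  # s
    sample_dt: float  # s
    temperature_path: Callable[[np.ndarray], np.ndarray]
    events: tuple[BindingEvent, ...] = ()
    resistance_noise_sd: float = 0.05  # Ohm, electrical noise of the meter
    quantization_step: float = METER_STEP  # Ohm; 0 disables quantization
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if self.sample_dt <= 0:
            raise ConfigError("sample_dt must be > 0")
        if self.quantization_step < 0:
            raise ConfigError("quantization_step must be >= 0")
        if self.resistance_noise_sd < 0:
            raise ConfigError("resistance_noise_sd must be >= 0")
        self.events = tuple(self.events)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.sample_dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples, dtype=float) * self.sample_dt


@dataclass
class TraceSet:
    """Time-aligned simulated observables plus ground truth."""

    time: np.ndarray  # s
    t_true: np.ndarray  # degC
    r_oc: np.ndarray  # Ohm
    r_mcl: np.ndarray  # Ohm
    v_mcl: np.ndarray  # V (amplified bridge output)
    sigma_true: np.ndarray  # N/m

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("t_true", "r_oc", "r_mcl", "v_mcl", "sigma_true"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")
        if np.any(self.r_oc <= 0) or np.any(self.r_mcl <= 0):
            raise ValueError("resistances must be positive everywhere")


def quantize(r, step: float):
    """Round to the nearest multiple of ``step`` (half-up ties); identity for step 0."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step == 0:
        return r
    r_arr = np.asarray(r, dtype=float)
    q = np.floor(r_arr / step + 0.5) * step
    return float(q) if np.isscalar(r) or q.ndim == 0 else q


def simulate(
    scenario: SensorScenario,
    oc_curve: CalibrationCurve | None = None,
    mcl_curve: CalibrationCurve | None = None,
    bridge: BridgeConfig | None = None,
    k_sigma: float = K_SIGMA_DEFAULT,
) -> TraceSet:
    """Generate a raw trace for ``scenario``.

    Per sample: sigma_true superposes the binding events; the resistances are
    the calibration laws evaluated at the true temperature, plus the
    stress-induced change ``k_sigma * sigma_true`` on the cantilever arm,
    plus white Gaussian meter noise, then quantized to the meter step; V_MCL
    is the amplified quarter-bridge conversion of the cantilever resistance
    against the balance point (the true initial cantilever resistance when
    ``bridge.balance_r`` is None).

    Traces are bit-reproducible from ``scenario.seed``: the generator draws
    the on-chip noise vector first, then the cantilever noise vector.
    """
    oc_curve = oc_curve if oc_curve is not None else default_onchip_curve()
    mcl_curve = mcl_curve if mcl_curve is not None else default_mcl_curve()
    bridge = bridge if bridge is not None else BridgeConfig()

    time = scenario.times()
    t_true = np.asarray(scenario.temperature_path(time), dtype=float)
    lo, hi = float(t_true.min()), float(t_true.max())
    for curve in (oc_curve, mcl_curve):
        if lo < curve.t_min or hi > curve.t_max:
            logger.warning(
                "scenario %r temperature range [%g, %g] degC extrapolates the %s "
                "curve's [%g, %g] degC calibration band",
                scenario.name or "<unnamed>", lo, hi, curve.kind, curve.t_min, curve.t_max,
            )

    sigma_true = np.zeros_like(time)
    for event in scenario.events:
        sigma_true += event.stress(time)

    rng = np.random.default_rng(scenario.seed)
    eps_oc = rng.normal(0.0, scenario.resistance_noise_sd, time.size)
    eps_mcl = rng.normal(0.0, scenario.resistance_noise_sd, time.size)

    r_oc = quantize(evaluate(oc_curve, t_true) + eps_oc, scenario.quantization_step)
    r_mcl = quantize(
        evaluate(mcl_curve, t_true) + k_sigma * sigma_true + eps_mcl,
        scenario.quantization_step,
    )

    resolved = bridge if bridge.balance_r is not None else bridge.resolved(
        evaluate(mcl_curve, float(t_true[0]))
    )
    v_mcl = resistance_to_voltage(r_mcl - resolved.balance_r, resolved)

    return TraceSet(time=time, t_true=t_true, r_oc=np.asarray(r_oc),
                    r_mcl=np.asarray(r_mcl), v_mcl=np.asarray(v_mcl),
                    sigma_true=sigma_true)


def default_scenarios() -> dict[str, SensorScenario]:
    """Three seeded scenarios mirroring the reference experiments in shape.

    * ``fig7_ramp``: 30 min air ramp, 13.6 -> 40.7 degC, heavy meter noise
      (0.5 Ohm) -- the thermal-sensitivity benchmark.
    * ``fig8_liquid``: 7 h in liquid with a slow +-0.9 degC ambient swing
      (1.8 degC change over ~3 h), no binding.
    * ``fig9_crp``: 1 h CRP-like detection: one -3.1 N/m compressive binding
      event under a -2 degC ambient drift.
    """
    return {
        "fig7_ramp": SensorScenario(
            duration=1800.0, sample_dt=1.0,
            temperature_path=LinearRamp(13.6, 40.7, 1800.0),
            events=(), resistance_noise_sd=0.5, quantization_step=METER_STEP,
            seed=7, name="fig7_ramp",
        ),
        "fig8_liquid": SensorScenario(
            duration=25200.0, sample_dt=1.0,
            temperature_path=SineDrift(mean=25.0, amplitude=0.9, period=21600.0),
            events=(), resistance_noise_sd=0.05, quantization_step=METER_STEP,
            seed=8, name="fig8_liquid",
        ),
        "fig9_crp": SensorScenario(
            duration=3600.0, sample_dt=1.0,
            temperature_path=LinearRamp(25.0, 23.0, 3600.0),
            events=(BindingEvent(t_on=600.0, sigma_max=-3.1, tau_on=400.0),),
            resistance_noise_sd=0.05, quantization_step=METER_STEP,
            seed=9, name="fig9_crp",
        ),
    }
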