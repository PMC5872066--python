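"""Real-time thermal self-elimination of the cantilever signal.

The measurement chain is a quarter Wheatstone bridge at supply V feeding a
preamplifier (gain g) and a low-pass filter.  For a fractional resistance
change of the active arm, dR/R = -4 dV/V, i.e. the bridge output is

    dV = sign * (-V * dR / (4 * R_balance)) * g

The compensation flow per sample is:

    R_OC --(invert on-chip law)--> T_sys
         --(evaluate MCL law)----> R_MCL_predicted
         --(bridge)--------------> V_Com
    V_Out = V_MCL - V_Com

With a perfect calibration model the thermally induced part of V_MCL is
cancelled exactly and V_Out carries only the (bio)chemical signal.  The
residual thermal sensitivity -- the OLS slope of V_Out against temperature,
quoted pre-amplifier in microvolt per degC -- quantifies how well the
cancellation works.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .calibration import CalibrationCurve, evaluate, invert_branch
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BridgeConfig:
    """Quarter Wheatstone bridge + preamplifier settings.

    ``balance_r`` is the cantilever resistance at which the bridge is
    balanced; leave it ``None`` to have the pipeline balance at the first
    sample's inferred temperature.
    """

    supply_v: float = 0.3
    balance_r: float | None = None
    gain: float = 1000.0
    quarter_factor: float = 4.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.supply_v <= 0:
            raise ConfigError("supply_v must be > 0")
        if self.balance_r is not None and self.balance_r <= 0:
            raise ConfigError("balance_r must be > 0")
        if self.gain < 1:
            raise ConfigError("gain must be >= 1")
        if self.quarter_factor <= 0:
            raise ConfigError("quarter_factor must be > 0")
        if self.sign not in (1, -1):
            raise ConfigError("sign must be +1 or -1")

    def resolved(self, balance_r: float) -> "BridgeConfig":
        """Copy with ``balance_r`` fixed."""
        return replace(self, balance_r=float(balance_r))


@dataclass(frozen=True)
class FilterConfig:
    """Causal low-pass: ``order`` cascaded single-pole sections, DC gain 1."""

    cutoff_hz: float = 0.1
    sample_dt: float = 1.0
    order: int = 1

    def __post_init__(self) -> None:
        if self.sample_dt <= 0:
            raise ConfigError("sample_dt must be > 0")
        if not 0 < self.cutoff_hz < 1.0 / (2.0 * self.sample_dt):
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz violates Nyquist for dt={self.sample_dt} s"
            )
        if self.order < 1:
            raise ConfigError("order must be >= 1")


@dataclass
class CompensationResult:
    """Per-sample outputs of the compensation flow plus the summary metric."""

    time: np.ndarray  # s
    t_sys: np.ndarray  # degC, inferred from the on-chip resistor
    r_mcl_pred: np.ndarray  # Ohm, thermally predicted cantilever resistance
    v_com: np.ndarray  # V, predicted thermal bridge voltage
    v_out: np.ndarray  # V, compensated output
    residual_sensitivity: float  # uV/degC, pre-amplifier
    bridge: BridgeConfig  # with balance_r resolved

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("t_sys", "r_mcl_pred", "v_com", "v_out"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")


def resistance_to_voltage(delta_r, bridge: BridgeConfig):
    """Amplified quarter-bridge voltage for a resistance change ``delta_r``.

    Linear map: sign * (-supply_v * delta_r / (quarter_factor * balance_r)) * gain.
    """
    if bridge.balance_r is None:
        raise ConfigError("bridge balance_r is unresolved")
    return bridge.sign * (
        -bridge.supply_v * np.asarray(delta_r, dtype=float)
        / (bridge.quarter_factor * bridge.balance_r)
    ) * bridge.gain


def voltage_to_resistance(v, bridge: BridgeConfig):
    """Exact inverse of :func:`resistance_to_voltage`."""
    if bridge.balance_r is None:
        raise ConfigError("bridge balance_r is unresolved")
    return np.asarray(v, dtype=float) * (bridge.quarter_factor * bridge.balance_r) / (
        bridge.sign * (-bridge.supply_v) * bridge.gain
    )


def lowpass(series, cfg: FilterConfig) -> np.ndarray:
    """Causal discrete low-pass with -3 dB near ``cutoff_hz`` and DC gain 1.

    Each of the ``order`` identical sections is the discrete RC filter
    y[i] = y[i-1] + a * (x[i] - y[i-1]) with a = 1 - exp(-dt / RC),
    RC = 1 / (2 pi f_c) (exact pole mapping, so the step response matches the
    continuous RC filter at the sample instants), initialized at the first
    sample so a constant input passes through unchanged from i = 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    rc = 1.0 / (2.0 * np.pi * cfg.cutoff_hz)
    a = 1.0 - np.exp(-cfg.sample_dt / rc)
    y = x
    for _ in range(cfg.order):
        # lfilter with zi = (1-a)*x0 makes y[0] = a*x0 + (1-a)*x0 = x0
        y, _zf = sps.lfilter([a], [1.0, a - 1.0], y, zi=[(1.0 - a) * y[0]])
    return y


def residual_sensitivity(v_out, temperature, gain: float = 1.0) -> float:
    """OLS slope of the output voltage against temperature, in uV/degC.

    The slope is referenced to the pre-amplifier level by dividing out
    ``gain`` (the thermal-sensitivity figures of merit for a 0.3 V bridge are
    conventionally quoted before the x1000 preamplifier).
    """
    v = np.asarray(v_out, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if v.shape != t.shape:
        raise ValueError("v_out and temperature must have equal length")
    span = float(t.max() - t.min())
    if span == 0.0:
        raise ValueError("temperature span is zero; slope undefined")
    if span < 1.0:
        logger.warning("temperature span %.3g degC < 1 degC; slope is poorly conditioned", span)
    slope = spstats.linregress(t, v).slope
    return float(slope) * 1e6 / gain


def compensate_stream(
    r_oc,
    v_mcl,
    oc_curve: CalibrationCurve,
    mcl_curve: CalibrationCurve,
    bridge: BridgeConfig,
    filt: FilterConfig | None = None,
    *,
    time=None,
    t_ref=None,
) -> CompensationResult:
    """Run the thermal self-elimination flow over aligned series.

    Per sample: the on-chip resistance is inverted to the system temperature
    T_sys (monotonic-branch closed form; samples outside the calibration band
    are processed and logged rather than rejected, since streaming operation
    must survive noisy excursions), the MCL law predicts the thermally induced
    cantilever resistance, the bridge converts its deviation from the balance
    point to V_Com, and V_Out = V_MCL - V_Com.  If ``filt`` is given, V_Out is
    low-pass filtered.

    ``bridge.balance_r = None`` balances the bridge at the first sample's
    inferred temperature, which gives V_Com and V_MCL a common zero.

    ``t_ref``: optional reference-thermometer series; when present the
    residual sensitivity is regressed against it instead of the (noisier)
    inferred T_sys.
    """
    r_oc = np.asarray(r_oc, dtype=float)
    v_mcl = np.asarray(v_mcl, dtype=float)
    if r_oc.shape != v_mcl.shape:
        raise ValueError(
            f"r_oc (n={r_oc.size}) and v_mcl (n={v_mcl.size}) must be aligned"
        )
    if r_oc.size < 2:
        raise ValueError("need at least 2 samples")
    dt = filt.sample_dt if filt is not None else 1.0
    if time is None:
        time = np.arange(r_oc.size, dtype=float) * dt
    else:
        time = np.asarray(time, dtype=float)
        if time.shape != r_oc.shape:
            raise ValueError("time must be aligned with the data series")

    t_sys = invert_branch(oc_curve, r_oc)
    outside = (t_sys < oc_curve.t_min) | (t_sys > oc_curve.t_max)
    if np.any(outside):
        logger.warning(
            "%d of %d inferred temperatures fall outside the [%g, %g] degC "
            "calibration band (noisy thermometer or extrapolated run)",
            int(np.count_nonzero(outside)), t_sys.size, oc_curve.t_min, oc_curve.t_max,
        )
    resolved = bridge if bridge.balance_r is not None else bridge.resolved(
        evaluate(mcl_curve, float(t_sys[0]))
    )
    r_mcl_pred = evaluate(mcl_curve, t_sys)
    v_com = resistance_to_voltage(r_mcl_pred - resolved.balance_r, resolved)
    v_out = v_mcl - v_com
    if filt is not None:
        v_out = lowpass(v_out, filt)

    t_for_slope = np.asarray(t_ref, dtype=float) if t_ref is not None else t_sys
    sens = residual_sensitivity(v_out, t_for_slope, gain=resolved.gain)

    return CompensationResult(
        time=time, t_sys=t_sys, r_mcl_pred=r_mcl_pred,
        v_com=np.asarray(v_com, dtype=float), v_out=np.asarray(v_out, dtype=float),
        residual_sensitivity=sens, bridge=resolved,
    )
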