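"""Surface-stress quantification of compensated detection runs.

Molecular binding on the functionalized face of the cantilever changes the
in-plane surface stress (N/m; negative = compressive), bending the beam and
straining the embedded piezoresistor.  The compensated output voltage maps
back to a resistance change through the bridge relation and to a stress
change through the transduction constant ``k_sigma`` (Ohm per N/m):

    delta_sigma = voltage_to_resistance(V_out) / k_sigma

``k_sigma`` must be the same constant used when interpreting (or
simulating) the raw trace; the conversion is then exactly the inverse of
the stress injection, so its sign convention cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compensation import BridgeConfig, CompensationResult, voltage_to_resistance


@dataclass(frozen=True)
class StressParams:
    """Transduction constant and the bridge it is referenced to."""

    k_sigma: float  # Ohm per N/m
    bridge: BridgeConfig

    def __post_init__(self) -> None:
        if self.k_sigma == 0:
            raise ValueError("k_sigma must be non-zero")


@dataclass(frozen=True)
class DetectionSummary:
    """Endpoint summary of a detection run."""

    sigma_final: float  # N/m
    sign_label: str  # "compressive" | "tensile"
    v_out_final: float  # V, endpoint-minus-baseline voltage step
    baseline_window: float  # s

    def __post_init__(self) -> None:
        expected = "compressive" if self.sigma_final < 0 else "tensile"
        if self.sign_label != expected:
            raise ValueError(
                f"sign_label {self.sign_label!r} inconsistent with sigma_final={self.sigma_final}"
            )


def voltage_to_stress(v_out, params: StressParams):
    """Surface-stress change (N/m) for a compensated voltage change (V)."""
    return voltage_to_resistance(v_out, params.bridge) / params.k_sigma


def summarize_detection(
    result: CompensationResult,
    params: StressParams,
    baseline_window: float = 300.0,
) -> DetectionSummary:
    """Endpoint stress estimate of a run.

    The signal is read as the mean of the last ``baseline_window`` seconds
    minus the mean of the first ``baseline_window`` seconds of V_out, then
    converted to stress.  The run must be at least twice the window long.
    """
    time = np.asarray(result.time, dtype=float)
    v_out = np.asarray(result.v_out, dtype=float)
    span = time[-1] - time[0]
    if span < 2.0 * baseline_window:
        raise ValueError(
            f"run spans {span:.6g} s, shorter than twice the {baseline_window:.6g} s window"
        )
    head = time <= time[0] + baseline_window
    tail = time >= time[-1] - baseline_window
    v_final = float(v_out[tail].mean() - v_out[head].mean())
    sigma = float(voltage_to_stress(v_final, params))
    return DetectionSummary(
        sigma_final=sigma,
        sign_label="compressive" if sigma < 0 else "tensile",
        v_out_final=v_final,
        baseline_window=baseline_window,
    )
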