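"""Quadratic resistance-temperature calibration for piezoresistive sensors.

A fixed on-chip piezoresistor and the piezoresistor embedded in a free-standing
microcantilever (MCL) both change resistance with temperature.  Over the
calibration band each law is well described by an empirical quadratic

    R(T) = c2 * T**2 + c1 * T + c0        [Ohm, T in degC]

The on-chip resistor sees only the temperature coefficient of resistance
(TCR); the suspended MCL resistor additionally bends with temperature
(bimorph effect), so the two devices carry distinct coefficients.  This
module fits, evaluates and inverts those laws, and computes the statistics
used to qualify the on-chip resistor as a thermometer (agreement with a
reference thermometer, hysteresis band over up/down temperature sweeps,
sweep-to-sweep coefficient of variation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import AmbiguityError, IdentifiabilityError, MonotonicityError, OutOfRangeError

logger = logging.getLogger(__name__)

CurveKind = Literal["on_chip", "mcl"]

#: Empirical quadratic coefficients (c2, c1, c0) of the reference device,
#: measured over a 20-70 degC thermal sweep: on-chip fixed piezoresistor
#: (TCR only) and suspended MCL piezoresistor (TCR + bimorph).
ONCHIP_COEFFS = (1.422e-3, 8.428e-2, 2719.0)
MCL_COEFFS = (1.085e-3, 9.861e-1, 2667.0)

#: Calibration band of the reference device (degC).
CAL_T_MIN = 20.0
CAL_T_MAX = 70.0

#: How far beyond the calibration band `invert` tolerates (degC), with a warning.
DEFAULT_INVERT_MARGIN = 5.0


@dataclass(frozen=True)
class CalibrationCurve:
    """A strictly monotonic quadratic R(T) law valid on [t_min, t_max].

    Parameters
    ----------
    kind
        ``"on_chip"`` for the fixed thermometer resistor, ``"mcl"`` for the
        suspended cantilever resistor.
    c2, c1, c0
        Quadratic, linear and constant coefficients (Ohm/degC^2, Ohm/degC, Ohm).
    t_min, t_max
        Temperature band (degC) over which the law was calibrated.
    rms_residual
        Root-mean-square fit residual (Ohm); 0 for exact/declared laws.
    """

    kind: CurveKind
    c2: float
    c1: float
    c0: float
    t_min: float
    t_max: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("on_chip", "mcl"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if not self.t_min < self.t_max:
            raise ValueError(f"t_min ({self.t_min}) must be < t_max ({self.t_max})")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")
        d_lo = 2.0 * self.c2 * self.t_min + self.c1
        d_hi = 2.0 * self.c2 * self.t_max + self.c1
        if d_lo == 0.0 or d_hi == 0.0 or math.copysign(1.0, d_lo) != math.copysign(1.0, d_hi):
            raise MonotonicityError(
                "curve is not strictly monotonic on "
                f"[{self.t_min}, {self.t_max}] degC (dR/dT changes sign)"
            )

    @property
    def increasing(self) -> bool:
        """True if R grows with T on the calibration band."""
        return 2.0 * self.c2 * self.t_min + self.c1 > 0

    def resistance_band(self) -> tuple[float, float]:
        """(min, max) resistance attained on [t_min, t_max]."""
        lo = evaluate(self, self.t_min)
        hi = evaluate(self, self.t_max)
        return (min(lo, hi), max(lo, hi))


@dataclass
class CalibrationDataset:
    """(temperature, resistance) pairs from one or more thermal sweeps.

    ``sweep_direction`` optionally labels each point ``"up"`` / ``"down"``
    (or ``"mixed"``); it is used only by the hysteresis statistics.
    """

    temperatures: np.ndarray
    resistances: np.ndarray
    sweep_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.resistances = np.asarray(self.resistances, dtype=float)
        if self.temperatures.shape != self.resistances.shape:
            raise ValueError("temperatures and resistances must have equal length")
        if self.sweep_direction is not None:
            self.sweep_direction = np.asarray(self.sweep_direction, dtype=object)
            if self.sweep_direction.shape != self.temperatures.shape:
                raise ValueError("sweep_direction must have the same length as the data")
        if np.unique(self.temperatures).size < 3:
            raise IdentifiabilityError(
                "need at least 3 distinct temperatures to identify a quadratic"
            )

    @property
    def n(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class ThermometerStats:
    """Validation statistics for the on-chip thermometer."""

    percent_difference: float  # mean |est-ref|/|ref| * 100, in percent
    hysteresis_band: float  # half-range of resistance across sweeps, Ohm
    temperature_band: float  # hysteresis band mapped through dR/dT, degC
    coefficient_of_variation: float  # mean per-temperature CV across sweeps, percent

    def __post_init__(self) -> None:
        if self.percent_difference < 0 or self.coefficient_of_variation < 0:
            raise ValueError("percent metrics must be non-negative")


def default_onchip_curve(t_min: float = CAL_T_MIN, t_max: float = CAL_T_MAX) -> CalibrationCurve:
    """The reference device's on-chip (TCR-only) law."""
    c2, c1, c0 = ONCHIP_COEFFS
    return CalibrationCurve("on_chip", c2, c1, c0, t_min, t_max)


def default_mcl_curve(t_min: float = CAL_T_MIN, t_max: float = CAL_T_MAX) -> CalibrationCurve:
    """The reference device's suspended-MCL (TCR + bimorph) law."""
    c2, c1, c0 = MCL_COEFFS
    return CalibrationCurve("mcl", c2, c1, c0, t_min, t_max)


def fit_quadratic(data: CalibrationDataset, kind: CurveKind) -> CalibrationCurve:
    """Ordinary least-squares quadratic fit of R against T.

    The returned band [t_min, t_max] is the data's temperature extent and the
    fitted curve must be strictly monotonic on it.

    Raises
    ------
    IdentifiabilityError
        Fewer than 3 distinct temperatures, or a span below 5 degC.
    MonotonicityError
        The fitted quadratic is not strictly monotonic on the data range.
    """
    t = data.temperatures
    r = data.resistances
    span = float(t.max() - t.min())
    if span < 5.0:
        raise IdentifiabilityError(
            f"temperature span {span:.3g} degC is too short (need >= 5 degC)"
        )
    c0, c1, c2 = npoly.polyfit(t, r, 2)
    resid = r - npoly.polyval(t, [c0, c1, c2])
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        kind=kind, c2=float(c2), c1=float(c1), c0=float(c0),
        t_min=float(t.min()), t_max=float(t.max()), rms_residual=rms,
    )


def evaluate(curve: CalibrationCurve, t):
    """R(T) = c2*T**2 + c1*T + c0.  Accepts scalars or arrays.

    Evaluation outside [t_min, t_max] is permitted (the quadratic is defined
    everywhere) but logged as extrapolation.
    """
    t_arr = np.asarray(t, dtype=float)
    out_of_band = (t_arr < curve.t_min) | (t_arr > curve.t_max)
    if np.any(out_of_band):
        logger.warning(
            "evaluating %s curve outside its [%g, %g] degC band (%d sample(s))",
            curve.kind, curve.t_min, curve.t_max, int(np.count_nonzero(out_of_band)),
        )
    result = curve.c2 * t_arr**2 + curve.c1 * t_arr + curve.c0
    return float(result) if np.isscalar(t) or result.ndim == 0 else result


def _stable_roots(a: float, b: float, c, disc):
    """Roots of a x**2 + b x + c = 0 via the cancellation-free q-method.

    Returns (lower, upper).  ``c`` and ``disc`` (= b**2 - 4ac, assumed >= 0)
    may be arrays.  Remains accurate when ``a`` is many orders of magnitude
    below ``b`` (near-linear calibration laws), where the textbook formula
    loses the physical root to cancellation.
    """
    sqrt_d = np.sqrt(disc)
    q = -0.5 * (b + math.copysign(1.0, b) * sqrt_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = q / a
        r2 = np.where(q != 0.0, c / np.where(q != 0.0, q, 1.0), -b / (2.0 * a))
    return np.minimum(r1, r2), np.maximum(r1, r2)


def invert_branch(curve: CalibrationCurve, r):
    """Root of R(T) = r on the curve's monotonic branch, without band checks.

    This is the raw closed-form inversion used by the streaming compensation
    path, where a noisy sample outside the calibration band must be flagged
    but not abort the run.  Raises :class:`OutOfRangeError` only when no real
    root exists (resistance beyond the parabola's extremum).
    """
    r_arr = np.asarray(r, dtype=float)
    if curve.c2 == 0.0:  # degenerate linear law
        t = (r_arr - curve.c0) / curve.c1
        return float(t) if np.isscalar(r) or t.ndim == 0 else t
    disc = curve.c1**2 - 4.0 * curve.c2 * (curve.c0 - r_arr)
    bad = disc < 0
    if np.any(bad):
        idx = int(np.argmax(bad))
        r_bad = float(np.atleast_1d(r_arr)[idx]) if r_arr.ndim else float(r_arr)
        raise OutOfRangeError(
            f"no real root for resistance {r_bad:.6g} Ohm (sample {idx}): "
            "beyond the extremum of the calibration parabola"
        )
    root_lo, root_hi = _stable_roots(curve.c2, curve.c1, curve.c0 - r_arr, disc)
    vertex = -curve.c1 / (2.0 * curve.c2)
    # the calibration band lies entirely on one side of the vertex (monotonic)
    t = root_hi if curve.t_min > vertex else root_lo
    return float(t) if np.isscalar(r) or t.ndim == 0 else t


def invert(curve: CalibrationCurve, r: float, margin: float = DEFAULT_INVERT_MARGIN) -> float:
    """Temperature at which the curve takes resistance ``r`` (degC).

    Exactly one quadratic root can lie on the monotonic branch; a root is
    admissible if it falls in [t_min - margin, t_max + margin].  Outside the
    calibration band but inside the margin a warning is logged.

    Raises
    ------
    OutOfRangeError
        No admissible root (message names the resistance and the valid band).
    AmbiguityError
        Both roots admissible; only possible if the monotonicity invariant
        was bypassed.
    """
    lo, hi = curve.t_min - margin, curve.t_max + margin
    if curve.c2 == 0.0:
        roots = [(r - curve.c0) / curve.c1]
    else:
        disc = curve.c1**2 - 4.0 * curve.c2 * (curve.c0 - r)
        if disc < 0:
            r_lo, r_hi = curve.resistance_band()
            raise OutOfRangeError(
                f"resistance {r:.6g} Ohm has no real preimage; valid band is "
                f"[{r_lo:.6g}, {r_hi:.6g}] Ohm over [{curve.t_min}, {curve.t_max}] degC"
            )
        root_lo, root_hi = _stable_roots(curve.c2, curve.c1, curve.c0 - r, disc)
        roots = [float(root_lo), float(root_hi)]
        if not all(math.isfinite(t) for t in roots):
            # one root escapes to infinity for a near-linear law; drop it
            roots = [t for t in roots if math.isfinite(t)]
    admissible = [t for t in roots if lo <= t <= hi]
    if not admissible:
        r_lo, r_hi = curve.resistance_band()
        raise OutOfRangeError(
            f"resistance {r:.6g} Ohm maps to temperature(s) "
            f"{', '.join(f'{t:.4g}' for t in roots)} degC, outside the admissible "
            f"band [{lo:.6g}, {hi:.6g}] degC; valid resistance band is "
            f"[{r_lo:.6g}, {r_hi:.6g}] Ohm"
        )
    if len(admissible) > 1:
        raise AmbiguityError(
            f"both roots {admissible} degC are admissible for {r:.6g} Ohm; "
            "the calibration curve is not monotonic on the admissible band"
        )
    t = admissible[0]
    if not curve.t_min <= t <= curve.t_max:
        logger.warning(
            "inverted temperature %.4g degC lies outside the [%g, %g] degC "
            "calibration band (within the %g degC margin)",
            t, curve.t_min, curve.t_max, margin,
        )
    return t


def _grid_cells(temperatures: np.ndarray, grid_step: float) -> np.ndarray:
    """Integer cell index of each temperature on a ``grid_step`` grid."""
    return np.round(np.asarray(temperatures, dtype=float) / grid_step).astype(np.int64)


def thermometer_stats(
    estimated_t: Sequence[float],
    reference_t: Sequence[float],
    sweeps: Sequence[CalibrationDataset],
    grid_step: float = 0.1,
) -> ThermometerStats:
    """Thermometer validation statistics.

    * ``percent_difference``: mean of |est - ref| / |ref| in percent, over the
      paired temperature series (samples with a 0 degC reference are excluded
      from the relative metric with a warning).
    * ``hysteresis_band``: resistances from all sweeps are matched on a
      ``grid_step`` (default 0.1 degC) temperature grid; in each cell holding
      both up- and down-sweep points (or, without direction labels, >= 2
      points) the half-range (max - min)/2 is taken; the band is the mean
      half-range, in Ohm.
    * ``temperature_band``: the hysteresis band divided by |dR/dT| of a pooled
      quadratic fit at the median matched temperature, in degC.
    * ``coefficient_of_variation``: per grid cell, the mean resistance of each
      sweep is collected; cells covered by >= 2 sweeps contribute
      100 * std(ddof=1) / mean; the CV is the mean over cells, in percent.
    """
    est = np.asarray(estimated_t, dtype=float)
    ref = np.asarray(reference_t, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimated and reference series must have equal length")
    nonzero = ref != 0.0
    if not np.any(nonzero):
        raise ValueError("reference series is identically 0 degC; relative metric undefined")
    if not np.all(nonzero):
        logger.warning(
            "%d sample(s) with 0 degC reference excluded from the relative metric",
            int(np.count_nonzero(~nonzero)),
        )
    percent_difference = float(
        np.mean(np.abs(est[nonzero] - ref[nonzero]) / np.abs(ref[nonzero])) * 100.0
    )

    if len(sweeps) < 2:
        raise ValueError("need at least 2 sweeps for hysteresis/CV statistics")

    # hysteresis: pool all points, group on the temperature grid
    all_t = np.concatenate([s.temperatures for s in sweeps])
    all_r = np.concatenate([s.resistances for s in sweeps])
    all_dir = np.concatenate(
        [s.sweep_direction if s.sweep_direction is not None
         else np.full(s.n, None, dtype=object) for s in sweeps]
    )
    cells = _grid_cells(all_t, grid_step)
    have_dirs = any(s.sweep_direction is not None for s in sweeps)
    half_ranges = []
    matched_temps = []
    for cell in np.unique(cells):
        m = cells == cell
        if have_dirs:
            dirs = set(d for d in all_dir[m] if d is not None)
            if not {"up", "down"} <= dirs:
                continue
        elif np.count_nonzero(m) < 2:
            continue
        r_cell = all_r[m]
        half_ranges.append((r_cell.max() - r_cell.min()) / 2.0)
        matched_temps.append(all_t[m].mean())
    hysteresis_band = float(np.mean(half_ranges)) if half_ranges else 0.0

    pooled = CalibrationDataset(all_t, all_r)
    pooled_curve = fit_quadratic(pooled, "on_chip")
    t_mid = float(np.median(matched_temps)) if matched_temps else float(np.median(all_t))
    slope = abs(2.0 * pooled_curve.c2 * t_mid + pooled_curve.c1)
    temperature_band = hysteresis_band / slope if slope > 0 else math.inf

    # CV: per cell, one mean resistance per sweep, then std/mean across sweeps
    cvs = []
    sweep_cells = [_grid_cells(s.temperatures, grid_step) for s in sweeps]
    for cell in np.unique(cells):
        per_sweep = []
        for s, sc in zip(sweeps, sweep_cells):
            m = sc == cell
            if np.any(m):
                per_sweep.append(float(s.resistances[m].mean()))
        if len(per_sweep) >= 2:
            arr = np.asarray(per_sweep)
            cvs.append(100.0 * arr.std(ddof=1) / arr.mean())
    coefficient_of_variation = float(np.mean(cvs)) if cvs else 0.0

    return ThermometerStats(
        percent_difference=percent_difference,
        hysteresis_band=hysteresis_band,
        temperature_band=temperature_band,
        coefficient_of_variation=coefficient_of_variation,
    )


def with_band(curve: CalibrationCurve, t_min: float, t_max: float) -> CalibrationCurve:
    """Copy of ``curve`` re-declared valid on [t_min, t_max] (re-validated)."""
    return replace(curve, t_min=t_min, t_max=t_max)
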