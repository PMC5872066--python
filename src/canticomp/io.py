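"""File formats: unit-suffixed CSV series and calibration-law JSON.

Column names carry their unit (``_ohm``, ``_C``, ``_V``, ``_Npm``, ``_s``)
so files are unambiguous; CSV uses a decimal point, UTF-8, header row.
All writes are atomic (temp file in the target directory + rename), and
every numeric value round-trips exactly through write/read.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationDataset
from .compensation import CompensationResult
from .errors import SchemaError
from .sensor_sim import TraceSet

TRACE_COLUMNS = ["time_s", "t_true_C", "r_oc_ohm", "r_mcl_ohm", "v_mcl_V", "sigma_true_Npm"]
RUN_REQUIRED = ["time_s", "r_oc_ohm", "v_mcl_V"]
RUN_OPTIONAL = ["t_ref_C"]
COMP_COLUMNS = ["time_s", "t_sys_C", "r_mcl_pred_ohm", "v_com_V", "v_out_V"]
CAL_KEYS = {"kind", "c2", "c1", "c0", "t_min", "t_max", "rms_residual"}


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise SchemaError(f"{path}: time_s is not strictly increasing")
    return df


def _frame_to_csv_text(df: pd.DataFrame) -> str:
    # repr-based float formatting round-trips exactly through read_csv
    return df.to_csv(index=False)


# --- traces -----------------------------------------------------------------


def write_traces(traces: TraceSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": traces.time, "t_true_C": traces.t_true,
        "r_oc_ohm": traces.r_oc, "r_mcl_ohm": traces.r_mcl,
        "v_mcl_V": traces.v_mcl, "sigma_true_Npm": traces.sigma_true,
    })
    _atomic_write_text(path, _frame_to_csv_text(df))


def read_traces(path: str | Path) -> TraceSet:
    df = _read_csv(path, TRACE_COLUMNS)
    return TraceSet(
        time=df["time_s"].to_numpy(), t_true=df["t_true_C"].to_numpy(),
        r_oc=df["r_oc_ohm"].to_numpy(), r_mcl=df["r_mcl_ohm"].to_numpy(),
        v_mcl=df["v_mcl_V"].to_numpy(), sigma_true=df["sigma_true_Npm"].to_numpy(),
    )


# --- measurement runs -------------------------------------------------------


def read_run(path: str | Path) -> dict[str, np.ndarray | None]:
    """Measurement run: time, on-chip resistance, bridge voltage, optional
    reference temperature.  A missing optional column yields ``None``, never
    silent zeros.  Trace files are accepted: their ground-truth ``t_true_C``
    column serves as the reference temperature when no ``t_ref_C`` is given."""
    df = _read_csv(path, RUN_REQUIRED)
    if "t_ref_C" in df.columns:
        t_ref = df["t_ref_C"].to_numpy()
    elif "t_true_C" in df.columns:
        t_ref = df["t_true_C"].to_numpy()
    else:
        t_ref = None
    return {
        "time": df["time_s"].to_numpy(),
        "r_oc": df["r_oc_ohm"].to_numpy(),
        "v_mcl": df["v_mcl_V"].to_numpy(),
        "t_ref": t_ref,
    }


# --- calibration sweeps -----------------------------------------------------


def read_calibration_data(path: str | Path) -> CalibrationDataset:
    """CSV ``temperature_C,resistance_ohm[,sweep]``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in ("temperature_C", "resistance_ohm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column(s) {col}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    direction = df["sweep"].to_numpy(dtype=object) if "sweep" in df.columns else None
    return CalibrationDataset(
        temperatures=df["temperature_C"].to_numpy(),
        resistances=df["resistance_ohm"].to_numpy(),
        sweep_direction=direction,
    )


# --- calibration laws -------------------------------------------------------


def write_calibration(curve: CalibrationCurve, path: str | Path) -> None:
    payload = dataclasses.asdict(curve)
    _atomic_write_text(path, json.dumps(payload, indent=2) + "\n")


def read_calibration(path: str | Path) -> CalibrationCurve:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: calibration file must hold a JSON object")
    missing = CAL_KEYS - payload.keys()
    if missing:
        raise SchemaError(f"{path}: missing key(s) {', '.join(sorted(missing))}")
    extra = payload.keys() - CAL_KEYS
    if extra:
        raise SchemaError(f"{path}: unknown key(s) {', '.join(sorted(extra))}")
    try:
        return CalibrationCurve(
            kind=payload["kind"],
            c2=float(payload["c2"]), c1=float(payload["c1"]), c0=float(payload["c0"]),
            t_min=float(payload["t_min"]), t_max=float(payload["t_max"]),
            rms_residual=float(payload["rms_residual"]),
        )
    except (TypeError, ValueError) as exc:
        # includes MonotonicityError raised by the constructor
        if isinstance(exc, SchemaError):
            raise
        raise type(exc)(f"{path}: {exc}") from exc


# --- compensation output ----------------------------------------------------


def write_compensation(result: CompensationResult, path: str | Path,
                       summary_path: str | Path | None = None) -> None:
    df = pd.DataFrame({
        "time_s": result.time, "t_sys_C": result.t_sys,
        "r_mcl_pred_ohm": result.r_mcl_pred, "v_com_V": result.v_com,
        "v_out_V": result.v_out,
    })
    _atomic_write_text(path, _frame_to_csv_text(df))
    if summary_path is not None:
        summary = {
            "residual_sensitivity_uV_per_C": result.residual_sensitivity,
            "n_samples": int(len(result.time)),
            "t_span_C": float(np.max(result.t_sys) - np.min(result.t_sys)),
            "balance_r_ohm": result.bridge.balance_r,
        }
        _atomic_write_text(summary_path, json.dumps(summary, indent=2) + "\n")


def read_compensation_series(path: str | Path) -> dict[str, np.ndarray]:
    df = _read_csv(path, COMP_COLUMNS)
    return {c: df[c].to_numpy() for c in COMP_COLUMNS}


def write_json(payload: dict, path: str | Path) -> None:
    _atomic_write_text(path, json.dumps(payload, indent=2) + "\n")
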