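"""Core data model for Aeonose-style electronic-nose measurements.

A single breath measurement is a 3-way conductivity array: 64 temperature
steps (one heat-and-cool sweep of the micro-hotplate, 260-340 degC in 32
ascending plus 32 descending steps) x 36 measurement cycles x 3 metal-oxide
sensors.  This module defines the measurement and metadata containers, the
temperature schedule, long-format CSV readers/writers, and the preprocessing
(scaling) options searched during model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_STEPS = 64
N_CYCLES = 36
N_SENSORS = 3
TENSOR_SHAPE = (N_STEPS, N_CYCLES, N_SENSORS)
TEMP_MIN_C = 260.0
TEMP_MAX_C = 340.0

#: Serial numbers of the five devices used in the study.
KNOWN_SERIALS = (259, 309, 315, 362, 379)

SCALING_NAMES = (
    "none",
    "baseline_ratio",
    "log_baseline_ratio",
    "per_sensor_zscore",
    "per_measurement_minmax",
)

MEASUREMENT_COLUMNS = ["patient_id", "cycle", "step", "sensor", "conductivity"]
METADATA_COLUMNS = [
    "patient_id",
    "label",
    "device_serial",
    "age",
    "sex",
    "food_intake_lt4h",
    "currently_smoking",
    "pack_years",
    "tumor_stage",
]


class DataFormatError(ValueError):
    """Raised when a measurement or metadata file violates the contract."""


@dataclass(frozen=True)
class TemperatureSchedule:
    """Sensor hotplate temperature program: 32 steps up, 32 steps down."""

    temps: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.temps
        if len(t) != N_STEPS:
            raise ValueError(f"temperature schedule must have {N_STEPS} values, got {len(t)}")
        if min(t) != TEMP_MIN_C or max(t) != TEMP_MAX_C:
            raise ValueError("temperature schedule must span 260-340 degC")
        for i in range(N_STEPS):
            if t[i] != t[N_STEPS - 1 - i]:
                raise ValueError("temperature schedule must be mirror-symmetric")


def make_temperature_schedule() -> TemperatureSchedule:
    """Build the 64-point schedule: 32 evenly spaced ascending values from
    260 to 340 degC inclusive, followed by their mirror image."""
    ascending = np.linspace(TEMP_MIN_C, TEMP_MAX_C, N_STEPS // 2)
    temps = tuple(ascending) + tuple(ascending[::-1])
    return TemperatureSchedule(temps=temps)


@dataclass
class Measurement:
    """One patient's breath measurement: a 64 x 36 x 3 conductivity tensor."""

    patient_id: str
    label: str
    device_serial: int
    tensor: np.ndarray

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != TENSOR_SHAPE:
            raise ValueError(
                f"measurement tensor for {self.patient_id!r} has shape "
                f"{self.tensor.shape}, expected {TENSOR_SHAPE}"
            )
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError(f"non-finite conductivity in measurement {self.patient_id!r}")
        if np.any(self.tensor <= 0):
            idx = tuple(int(v) for v in np.argwhere(self.tensor <= 0)[0])
            raise ValueError(
                f"non-positive conductivity in measurement {self.patient_id!r} "
                f"at (step, cycle, sensor)={idx}"
            )
        if int(self.device_serial) not in KNOWN_SERIALS:
            raise ValueError(
                f"unknown device serial {self.device_serial} for patient "
                f"{self.patient_id!r}; known serials: {KNOWN_SERIALS}"
            )
        self.device_serial = int(self.device_serial)


@dataclass(frozen=True)
class PatientMetadata:
    patient_id: str
    label: str
    device_serial: int
    age: float
    sex: str
    food_intake_lt4h: bool
    currently_smoking: bool
    pack_years: float
    tumor_stage: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.pack_years < 0:
            raise ValueError("pack_years must be non-negative")
        if self.tumor_stage not in (0, 1, 2, 3, 4):
            raise ValueError(f"tumor_stage must be in 0..4, got {self.tumor_stage}")


# ---------------------------------------------------------------------------
# Scaling / preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ScalingOption:
    """A fitted preprocessing transform applied to measurement tensors.

    ``baseline_ratio`` and ``log_baseline_ratio`` are per-measurement
    (each sensor trace is divided by that sensor's mean over cycle 0);
    ``per_sensor_zscore`` carries per-sensor mean/sd fitted on training
    measurements only; ``per_measurement_minmax`` rescales each tensor to
    [0, 1].
    """

    name: str
    sensor_mean: np.ndarray | None = None
    sensor_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in SCALING_NAMES:
            raise ValueError(f"unknown scaling option {self.name!r}; choose from {SCALING_NAMES}")


def fit_scaling(training: Sequence[Measurement] | Sequence[np.ndarray], name: str) -> ScalingOption:
    """Fit a scaling option on training measurements only.

    Only ``per_sensor_zscore`` has fitted parameters; the other options are
    stateless but still go through this interface so the caller cannot leak
    test data by accident.
    """
    opt = ScalingOption(name=name)
    if name != "per_sensor_zscore":
        return opt
    if len(training) == 0:
        raise ValueError("per_sensor_zscore requires at least one training measurement")
    stack = np.stack([_tensor_of(m) for m in training])  # (n, 64, 36, 3)
    mean = stack.mean(axis=(0, 1, 2))
    std = stack.std(axis=(0, 1, 2), ddof=0)
    if np.any(std == 0):
        raise ValueError("zero training variance for at least one sensor; cannot z-score")
    opt.sensor_mean = mean
    opt.sensor_std = std
    return opt


def _tensor_of(m: Measurement | np.ndarray) -> np.ndarray:
    return m.tensor if isinstance(m, Measurement) else np.asarray(m, dtype=float)


def apply_scaling(option: ScalingOption, measurement: Measurement | np.ndarray) -> np.ndarray:
    """Apply a fitted scaling option to one measurement tensor.

    Reads nothing beyond its arguments, so scaled outputs are invariant to
    the order in which measurements are processed.
    """
    x = _tensor_of(measurement)
    if x.shape != TENSOR_SHAPE:
        raise ValueError(f"tensor shape {x.shape} != {TENSOR_SHAPE}")
    name = option.name
    if name == "none":
        return x.copy()
    if name in ("baseline_ratio", "log_baseline_ratio"):
        baseline = x[:, 0, :].mean(axis=0)  # per-sensor mean over cycle 0
        if np.any(baseline == 0):
            raise ValueError("zero cycle-0 baseline mean; cannot form baseline ratio")
        out = x / baseline[None, None, :]
        if name == "log_baseline_ratio":
            if np.any(out <= 0):
                raise ValueError("log_baseline_ratio requires strictly positive ratios")
            out = np.log(out)
        return out
    if name == "per_sensor_zscore":
        if option.sensor_mean is None or option.sensor_std is None:
            raise ValueError("per_sensor_zscore option was not fitted")
        return (x - option.sensor_mean[None, None, :]) / option.sensor_std[None, None, :]
    if name == "per_measurement_minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("constant tensor cannot be min-max scaled")
        return (x - lo) / (hi - lo)
    raise ValueError(f"unknown scaling option {name!r}")


# ---------------------------------------------------------------------------
# File I/O (long-format CSV)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # >= 9 significant digits round-trips conductivities


def write_measurements(
    measurements: Sequence[Measurement],
    metadata: Sequence[PatientMetadata],
    measurement_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a cohort as two CSV files (long-format tensor + metadata)."""
    rows = []
    for m in measurements:
        step_ix, cyc_ix, sen_ix = np.meshgrid(
            np.arange(N_STEPS), np.arange(N_CYCLES), np.arange(N_SENSORS), indexing="ij"
        )
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": m.patient_id,
                    "cycle": cyc_ix.ravel(),
                    "step": step_ix.ravel(),
                    "sensor": sen_ix.ravel(),
                    "conductivity": m.tensor.ravel(),
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    )
    df.to_csv(measurement_path, index=False, float_format=_FLOAT_FMT)

    meta_df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "device_serial": p.device_serial,
                "age": p.age,
                "sex": p.sex,
                "food_intake_lt4h": p.food_intake_lt4h,
                "currently_smoking": p.currently_smoking,
                "pack_years": p.pack_years,
                "tumor_stage": p.tumor_stage,
            }
            for p in metadata
        ],
        columns=METADATA_COLUMNS,
    )
    meta_df.to_csv(metadata_path, index=False, float_format=_FLOAT_FMT)


def read_measurements(
    measurement_path: str | Path, metadata_path: str | Path
) -> tuple[list[Measurement], list[PatientMetadata]]:
    """Read a cohort written by :func:`write_measurements`.

    Rejects missing cells, duplicate keys, unknown serials and non-positive
    conductivities with a message naming the offending patient and index.
    """
    df = pd.read_csv(measurement_path)
    missing_cols = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise DataFormatError(f"measurement file missing columns {sorted(missing_cols)}")
    meta_df = pd.read_csv(metadata_path)
    missing_cols = set(METADATA_COLUMNS) - set(meta_df.columns)
    if missing_cols:
        raise DataFormatError(f"metadata file missing columns {sorted(missing_cols)}")
    if meta_df["patient_id"].duplicated().any():
        dup = meta_df.loc[meta_df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DataFormatError(f"duplicate patient_id {dup!r} in metadata")

    metadata = [
        PatientMetadata(
            patient_id=str(r.patient_id),
            label=str(r.label),
            device_serial=int(r.device_serial),
            age=float(r.age),
            sex=str(r.sex),
            food_intake_lt4h=_to_bool(r.food_intake_lt4h),
            currently_smoking=_to_bool(r.currently_smoking),
            pack_years=float(r.pack_years),
            tumor_stage=int(r.tumor_stage),
        )
        for r in meta_df.itertuples(index=False)
    ]
    meta_by_id = {p.patient_id: p for p in metadata}
    for p in metadata:
        if p.device_serial not in KNOWN_SERIALS:
            raise DataFormatError(
                f"unknown device serial {p.device_serial} for patient {p.patient_id!r}"
            )

    measurements: list[Measurement] = []
    expected = N_STEPS * N_CYCLES * N_SENSORS
    for pid, grp in df.groupby("patient_id", sort=False):
        pid = str(pid)
        if pid not in meta_by_id:
            raise DataFormatError(f"measurement rows for {pid!r} have no metadata row")
        steps = grp["step"].to_numpy(dtype=int)
        cycles = grp["cycle"].to_numpy(dtype=int)
        sensors = grp["sensor"].to_numpy(dtype=int)
        if (
            steps.min(initial=0) < 0 or steps.max(initial=0) >= N_STEPS
            or cycles.min(initial=0) < 0 or cycles.max(initial=0) >= N_CYCLES
            or sensors.min(initial=0) < 0 or sensors.max(initial=0) >= N_SENSORS
        ):
            raise DataFormatError(f"out-of-range index for patient {pid!r}")
        flat = steps * (N_CYCLES * N_SENSORS) + cycles * N_SENSORS + sensors
        counts = np.bincount(flat, minlength=expected)
        if np.any(counts > 1):
            i = int(np.argmax(counts > 1))
            raise DataFormatError(
                f"duplicate cell for patient {pid!r} at "
                f"(step={i // (N_CYCLES * N_SENSORS)}, "
                f"cycle={(i // N_SENSORS) % N_CYCLES}, sensor={i % N_SENSORS})"
            )
        if np.any(counts == 0):
            i = int(np.argmax(counts == 0))
            raise DataFormatError(
                f"missing cell for patient {pid!r} at "
                f"(step={i // (N_CYCLES * N_SENSORS)}, "
                f"cycle={(i // N_SENSORS) % N_CYCLES}, sensor={i % N_SENSORS})"
            )
        tensor = np.empty(expected)
        tensor[flat] = grp["conductivity"].to_numpy(dtype=float)
        tensor = tensor.reshape(TENSOR_SHAPE)
        bad = ~np.isfinite(tensor) | (tensor <= 0)
        if np.any(bad):
            idx = tuple(int(v) for v in np.argwhere(bad)[0])
            raise DataFormatError(
                f"non-positive or non-finite conductivity for patient {pid!r} "
                f"at (step, cycle, sensor)={idx}"
            )
        meta = meta_by_id[pid]
        measurements.append(
            Measurement(
                patient_id=pid,
                label=meta.label,
                device_serial=meta.device_serial,
                tensor=tensor,
            )
        )
    measured_ids = {m.patient_id for m in measurements}
    for p in metadata:
        if p.patient_id not in measured_ids:
            raise DataFormatError(f"metadata row for {p.patient_id!r} has no measurement rows")
    return measurements, metadata


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise DataFormatError(f"cannot parse boolean value {v!r}")
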