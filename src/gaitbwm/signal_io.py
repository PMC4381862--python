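"""Recording and step-table I/O.

The package standardises on a plain-text interchange format: a CSV with a
``time_s`` column plus three acceleration columns (``ax, ay, az``, or with a
``_g`` suffix when recorded in gravity units), optionally accompanied by a
YAML metadata sidecar carrying ``sample_rate_hz``, ``units``,
``vertical_axis``, ``sensor_height_m`` and ``first_foot``.

All accelerations are held internally in m/s²; g-unit input is converted at
read time (1 g = 9.80665 m/s²).  Event times are absolute seconds into the
recording, 0-based at the first sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

G = 9.80665  # m/s² per g

#: canonical step-table column order
STEP_COLUMNS = [
    "bout_id",
    "pass_id",
    "on_walkway",
    "foot",
    "step_time",
    "stride_time",
    "stance_time",
    "swing_time",
    "step_length",
    "step_velocity",
]


class FormatError(ValueError):
    """Malformed recording or table file."""


class EmptyInputError(ValueError):
    """Input contains too few samples to be usable."""


@dataclass
class AccelerometerRecording:
    """Uniformly sampled tri-axial acceleration.

    Parameters
    ----------
    samples : ndarray, shape (n, 3)
        Acceleration in m/s², one column per axis.
    sample_rate : float
        Sampling frequency in Hz.
    vertical_axis : int
        Column index of the vertical (cranio-caudal) axis ``a_v``.
    sensor_height : float or None
        Sensor height above ground in metres — the pendulum length used by
        the inverted-pendulum step-length model.  Required only when step
        length is to be computed.
    start_time : float
        Time of the first sample in seconds (default 0).
    meta : dict
        Free-form subject / session labels (e.g. ``first_foot``, ``group``).
    """

    samples: np.ndarray
    sample_rate: float
    vertical_axis: int = 2
    sensor_height: float | None = None
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError("samples must be an (n, 3) array")
        if self.samples.shape[0] < 2:
            raise EmptyInputError("recording needs at least 2 samples")
        if not 0 <= self.vertical_axis <= 2:
            raise ValueError("vertical_axis must be 0, 1 or 2")
        if self.sensor_height is not None and self.sensor_height <= 0:
            raise ValueError("sensor_height must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    @property
    def av(self) -> np.ndarray:
        """Vertical acceleration channel, m/s²."""
        return self.samples[:, self.vertical_axis]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class ReaderConfig:
    """Options controlling recording ingestion.

    ``units`` may be "auto" (infer from column suffixes / sidecar), "g" or
    "m/s2".  ``max_jitter_fraction`` is the largest tolerated deviation of
    any timestamp from the uniform grid before the signal is resampled by
    linear interpolation (with a warning).
    """

    units: str = "auto"
    vertical_axis: int | str = "auto"
    sample_rate: float | None = None
    sensor_height: float | None = None
    max_jitter_fraction: float = 0.10


def _load_sidecar(path: Path) -> dict:
    for candidate in (path.with_suffix(".yaml"), path.parent / "meta.yaml"):
        if candidate.exists():
            with open(candidate) as fh:
                return yaml.safe_load(fh) or {}
    return {}


def read_recording(path: str | Path, config: ReaderConfig | None = None) -> AccelerometerRecording:
    """Read a recording CSV (plus optional YAML sidecar) into m/s².

    Raises :class:`FormatError` on missing acceleration columns or a
    non-monotonic time column, :class:`EmptyInputError` below 2 samples.
    """
    config = config or ReaderConfig()
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _load_sidecar(path)

    axis_cols, in_g = _find_axis_columns(df.columns)
    units = config.units
    if units == "auto":
        units = sidecar.get("units", "g" if in_g else "m/s2")

    if len(df) < 2:
        raise EmptyInputError(f"{path}: fewer than 2 samples")

    sample_rate = config.sample_rate or sidecar.get("sample_rate_hz")
    data = df[axis_cols].to_numpy(dtype=float)

    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time_s is not strictly increasing")
        interval = np.median(dt)
        if sample_rate is None:
            sample_rate = 1.0 / interval
        grid = t[0] + np.arange(len(t)) / sample_rate
        jitter = np.max(np.abs(t - grid))
        if jitter > config.max_jitter_fraction / sample_rate:
            warnings.warn(
                f"{path}: timestamp jitter {jitter:.4g}s exceeds "
                f"{config.max_jitter_fraction:.0%} of the sample interval; "
                "resampling by linear interpolation",
                stacklevel=2,
            )
            data = np.column_stack([np.interp(grid, t, data[:, j]) for j in range(3)])
        start_time = float(t[0])
    else:
        if sample_rate is None:
            raise FormatError(f"{path}: no time_s column and no sample rate declared")
        start_time = 0.0

    if units == "g":
        data = data * G
    elif units not in ("m/s2", "m/s^2", "ms2"):
        raise FormatError(f"unknown units {units!r}")

    vertical = config.vertical_axis
    if vertical == "auto":
        vertical = sidecar.get("vertical_axis", 2)
    if isinstance(vertical, str):
        vertical = axis_cols.index(_match_axis_column(axis_cols, vertical))

    meta = {k: v for k, v in sidecar.items() if k not in ("sample_rate_hz", "units", "vertical_axis", "sensor_height_m")}
    sensor_height = config.sensor_height or sidecar.get("sensor_height_m")
    return AccelerometerRecording(
        samples=data,
        sample_rate=float(sample_rate),
        vertical_axis=int(vertical),
        sensor_height=sensor_height,
        start_time=start_time,
        meta=meta,
    )


def _find_axis_columns(columns) -> tuple[list[str], bool]:
    cols = list(columns)
    for names, in_g in ((["ax", "ay", "az"], False), (["ax_g", "ay_g", "az_g"], True), (["av"], False), (["av_g"], True)):
        if all(n in cols for n in names):
            if len(names) == 1:  # vertical-only recording: pad lateral axes with zeros downstream
                continue
            return names, in_g
    raise FormatError(f"no acceleration columns found among {cols}")


def _match_axis_column(axis_cols: list[str], name: str) -> str:
    for c in axis_cols:
        if c == name or c == f"{name}_g":
            return c
    # "av" conventionally maps to the z (cranio-caudal) axis when unnamed
    if name == "av":
        return axis_cols[2]
    raise FormatError(f"vertical axis {name!r} not among {axis_cols}")


def write_recording(rec: AccelerometerRecording, path: str | Path, sidecar: bool = True) -> None:
    """Write a recording to CSV (m/s²) with an optional YAML metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.times,
            "ax": rec.samples[:, 0],
            "ay": rec.samples[:, 1],
            "az": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False)
    if sidecar:
        meta = {
            "sample_rate_hz": rec.sample_rate,
            "units": "m/s2",
            "vertical_axis": rec.vertical_axis,
            **({"sensor_height_m": rec.sensor_height} if rec.sensor_height else {}),
            **rec.meta,
        }
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def empty_step_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("object" if c in ("foot", "on_walkway") else "float")) for c in STEP_COLUMNS})


def validate_step_table(table: pd.DataFrame, bounds: tuple[float, float] = (0.25, 2.25)) -> None:
    """Check the structural invariants of a per-step table.

    Every surviving step time must lie within the physiological window,
    stride(k) must equal step(k) + step(k+1) for consecutive steps of the
    same bout, and stance + swing must reconstruct the stride of the same
    foot where all three are present.
    """
    st = table["step_time"].dropna()
    if len(st) and ((st < bounds[0]).any() or (st > bounds[1]).any()):
        raise ValueError("step_time outside the physiological window")
    for _, bout in table.groupby("bout_id"):
        step = bout["step_time"].to_numpy(float)
        stride = bout["stride_time"].to_numpy(float)
        for k in range(len(bout) - 1):
            if np.isfinite(stride[k]) and np.isfinite(step[k]) and np.isfinite(step[k + 1]):
                if abs(stride[k] - (step[k] + step[k + 1])) > 1e-9:
                    raise ValueError("stride_time != step_time(k) + step_time(k+1)")
        stance = bout["stance_time"].to_numpy(float)
        swing = bout["swing_time"].to_numpy(float)
        ok = np.isfinite(stance) & np.isfinite(swing) & np.isfinite(stride)
        if np.any(np.abs(stance[ok] + swing[ok] - stride[ok]) > 1e-9):
            raise ValueError("stance_time + swing_time != stride_time")


def write_step_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a step table as CSV with the canonical column order."""
    out = table.copy()
    for c in STEP_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    out[STEP_COLUMNS].to_csv(path, index=False)


def read_step_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STEP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"step table missing columns {sorted(missing)}")
    return df[STEP_COLUMNS]
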