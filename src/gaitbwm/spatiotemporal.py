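"""Per-step spatio-temporal parameters.

Temporal parameters follow the gait-cycle geometry: with ICs indexed k in
walking order,

* step time(k)   = IC(k+1) − IC(k)
* stride time(k) = IC(k+2) − IC(k)
* stance time of the foot striking at IC(k) = FC of that foot − IC(k),
  where its FC is the one just after the contralateral IC(k+1)
* swing time = next same-foot IC − FC, so stance + swing = stride exactly.

Step length uses the inverted-pendulum model: during single support the
centre of mass vaults over the stance leg on a circular arc of radius l
(the sensor height above ground).  If the CoM rises by h within a step, the
chord geometry gives

    step length = 2 · sqrt(2·l·h − h²)

h is measured by double integration of the vertical acceleration with a
per-step linear detrend to suppress integration drift.  Step velocity is
step length / step time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .event_detection import GaitEventSeries
from .signal_io import STEP_COLUMNS, AccelerometerRecording

__all__ = [
    "compute_temporal_params",
    "estimate_vertical_excursion",
    "step_length",
    "h_from_length",
    "step_velocity",
    "segment_passes",
    "extract_step_table",
]


def compute_temporal_params(series: GaitEventSeries) -> pd.DataFrame:
    """Build the per-step table of temporal parameters from labelled events.

    One row per step, anchored at IC(k) for k = 0..n_IC−2 within each bout;
    the row's foot is the foot striking at IC(k).  Quantities that need
    events beyond the bout edge (stride of the last step, stance/swing of
    the last two) are left absent, as are stance/swing when feet are
    unlabelled or the expected FC is missing.
    """
    rows = []
    for bout_id, (start, stop) in enumerate(series.bouts):
        ev = series.bout_events((start, stop))
        ics = ev[ev["kind"] == "IC"].reset_index(drop=True)
        fcs = ev[ev["kind"] == "FC"]
        ic_t = ics["time"].to_numpy(float)
        ic_f = ics["foot"].to_numpy()
        fc_t = fcs["time"].to_numpy(float)
        fc_m = fcs["magnitude"].to_numpy(float)
        for k in range(len(ic_t) - 1):
            step = ic_t[k + 1] - ic_t[k]
            stride = ic_t[k + 2] - ic_t[k] if k + 2 < len(ic_t) else np.nan
            stance = swing = np.nan
            if ic_f[k] in ("L", "R") and k + 2 < len(ic_t):
                # FC of this foot lies between the contralateral IC(k+1)
                # and the next same-foot IC(k+2); strongest candidate wins
                in_window = (fc_t > ic_t[k + 1]) & (fc_t < ic_t[k + 2])
                if in_window.any():
                    fc = fc_t[in_window][np.argmax(fc_m[in_window])]
                    stance = fc - ic_t[k]
                    swing = ic_t[k + 2] - fc
            rows.append(
                {
                    "bout_id": bout_id,
                    "pass_id": np.nan,
                    "on_walkway": np.nan,
                    "foot": ic_f[k] if ic_f[k] in ("L", "R") else "unknown",
                    "step_time": step,
                    "stride_time": stride,
                    "stance_time": stance,
                    "swing_time": swing,
                    "step_length": np.nan,
                    "step_velocity": np.nan,
                }
            )
    if not rows:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.DataFrame(rows, columns=STEP_COLUMNS)


def estimate_vertical_excursion(
    recording: AccelerometerRecording, series: GaitEventSeries
) -> np.ndarray:
    """CoM vertical excursion h (metres) per step window.

    The mean-removed vertical acceleration is integrated twice
    (trapezoidal); within each IC-to-IC window the displacement is linearly
    detrended between the window endpoints to suppress the low-frequency
    drift that double integration accumulates, and h is the max−min of the
    detrended displacement.  Windows shorter than 3 samples give NaN.
    Returned in step-table row order (one value per step row).
    """
    fs = recording.sample_rate
    av = recording.av - recording.av.mean()
    vel = cumulative_trapezoid(av, dx=1.0 / fs, initial=0.0)
    disp = cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0)
    t0 = recording.start_time

    hs: list[float] = []
    for bout in series.bouts:
        ev = series.bout_events(bout)
        ic_t = ev[ev["kind"] == "IC"]["time"].to_numpy(float)
        for k in range(len(ic_t) - 1):
            i0 = int(round((ic_t[k] - t0) * fs))
            i1 = int(round((ic_t[k + 1] - t0) * fs))
            i0, i1 = max(i0, 0), min(i1, len(disp) - 1)
            if i1 - i0 < 2:
                hs.append(np.nan)
                continue
            w = disp[i0 : i1 + 1]
            trend = np.linspace(w[0], w[-1], len(w))
            detrended = w - trend
            hs.append(float(detrended.max() - detrended.min()))
    return np.asarray(hs, dtype=float)


def step_length(l: float, h, correction: float = 1.0):
    """Inverted-pendulum step length in cm: correction · 2·√(2·l·h − h²).

    ``l`` is the pendulum (sensor) height in metres and ``h`` the per-step
    CoM vertical excursion in metres; accepts scalars or arrays.  Excursions
    outside [0, l] are geometrically impossible for the model and yield NaN
    (the step is flagged invalid); h = l gives the geometric maximum 2·l.
    The optional correction factor (for the systematic inverted-pendulum
    underestimate) is explicit and defaults to 1.
    """
    if l <= 0:
        raise ValueError("pendulum length must be positive")
    if correction < 0:
        raise ValueError("correction factor must be non-negative")
    h = np.asarray(h, dtype=float)
    valid = (h >= 0) & (h <= l)
    with np.errstate(invalid="ignore"):
        sl = np.where(valid, 2.0 * np.sqrt(np.clip(2.0 * l * h - h * h, 0.0, None)), np.nan)
    out = correction * sl * 100.0
    return float(out) if out.ndim == 0 else out


def h_from_length(l: float, step_length_m) -> np.ndarray | float:
    """Invert the pendulum chord: h = l − √(l² − SL²/4) (metres in, metres out)."""
    sl = np.asarray(step_length_m, dtype=float)
    out = l - np.sqrt(l * l - sl * sl / 4.0)
    return float(out) if out.ndim == 0 else out


def step_velocity(step_length_cm, step_time_s):
    """Step velocity in cm/s; absent (NaN) where length or time is absent or zero."""
    sl = np.asarray(step_length_cm, dtype=float)
    st = np.asarray(step_time_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(np.isfinite(sl) & np.isfinite(st) & (st > 0), sl / st, np.nan)
    return float(v) if v.ndim == 0 else v


def segment_passes(
    table: pd.DataFrame, pass_counts: list[int], on_walkway: list[bool] | None = None
) -> pd.DataFrame:
    """Assign steps to walkway passes / circuit segments by step counts.

    In the original protocol the instrumented walkway samples gait only
    while the subject traverses the mat, so the continuous accelerometer
    step sequence is cut into alternating on/off-walkway segments using
    externally counted steps.  Steps beyond the supplied counts go to a
    trailing off-walkway segment.
    """
    counts = list(pass_counts)
    if any(c < 0 for c in counts):
        raise ValueError("pass counts must be non-negative")
    if on_walkway is None:
        on_walkway = [i % 2 == 0 for i in range(len(counts))]
    if len(on_walkway) != len(counts):
        raise ValueError("need one on/off label per pass count")
    out = table.copy().reset_index(drop=True)
    pass_id = np.full(len(out), np.nan)
    on = np.full(len(out), np.nan, dtype=object)
    i = 0
    for pid, (n, flag) in enumerate(zip(counts, on_walkway), start=1):
        pass_id[i : i + n] = pid
        on[i : i + n] = bool(flag)
        i += n
        if i >= len(out):
            break
    if i < len(out):
        pass_id[i:] = len(counts) + 1
        on[i:] = False
    out["pass_id"] = pass_id
    out["on_walkway"] = on
    return out


def extract_step_table(
    recording: AccelerometerRecording,
    series: GaitEventSeries,
    correction: float = 1.0,
) -> pd.DataFrame:
    """Temporal parameters plus pendulum step length and velocity per step."""
    table = compute_temporal_params(series)
    if len(table) and recording.sensor_height:
        h = estimate_vertical_excursion(recording, series)
        table["step_length"] = step_length(recording.sensor_height, h, correction)
        table["step_velocity"] = step_velocity(
            table["step_length"].to_numpy(), table["step_time"].to_numpy()
        )
    return table
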