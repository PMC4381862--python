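"""Gait event detection from lumbar vertical acceleration.

Initial contact (IC, heel strike) and final contact (FC, toe off) are
estimated with a smoothed-differentiation scheme: the vertical acceleration
``a_v`` (gravity removed by mean subtraction) is integrated to a velocity
trace, then differentiated with a Gaussian continuous wavelet transform.
ICs are the minima of the CWT coefficients — with the CWT sign convention
for an antisymmetric (odd) wavelet, these coincide with maxima of the
smoothed acceleration, where the centre of mass is caught by the leading
leg.  A second CWT differentiation yields a signal whose maxima mark FC
candidates.

Spurious IC candidates (scuffs, clothing artefacts) are rejected by
restricting consecutive-IC intervals to a physiological window, 0.25–2.25 s
by default; a gap longer than the upper bound splits the walk into separate
bouts, since no valid step can span it.

The sensor carries no gyroscope, so laterality cannot be sensed: the first
foot is external input (in the original protocol, read off a video) and
subsequent ICs alternate.  Each FC is assigned to the foot contralateral to
the IC it immediately follows, so that the stance of foot X runs from IC_X
to FC_X across the opposite foot's IC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .signal_io import AccelerometerRecording

__all__ = [
    "DetectorConfig",
    "GaitEventSeries",
    "cwt_differentiate",
    "cwt_detect_events",
    "filter_spurious_ics",
    "assign_feet",
    "count_steps",
]

EVENT_COLUMNS = ["time", "kind", "foot", "magnitude"]

_OPPOSITE = {"L": "R", "R": "L", "unknown": "unknown"}


@dataclass
class DetectorConfig:
    """Tunables of the event detector.

    wavelet : str
        Continuous wavelet used as the smoothing differentiator.  Default
        "gaus1" (first-derivative-of-Gaussian); any antisymmetric wavelet
        known to PyWavelets (e.g. higher-order "gausN", or a spline-family
        wavelet such as "fbsp1-1-1") may be substituted.
    scale : "auto" or float
        CWT scale in samples.  "auto" derives it from the dominant stride
        frequency of the integrated signal (FFT peak in 0.4–4 Hz), setting
        scale = sample_rate / (10 · f0) — roughly a tenth of a step period.
    ic_interval_bounds : (float, float)
        Physiological window for consecutive IC intervals in seconds.
    edge_guard_scales : float
        Extrema within this many scale-widths of the signal edges are
        discarded (wavelet edge effects).
    min_magnitude_fraction : float
        Candidates whose extremum magnitude falls below this fraction of
        the median candidate magnitude (per event kind) are rejected as
        noise — real step extrema cluster around a common scale, while
        sensor-noise extrema in quiet stretches sit far below it.
    """

    wavelet: str = "gaus1"
    scale: str | float = "auto"
    ic_interval_bounds: tuple[float, float] = (0.25, 2.25)
    edge_guard_scales: float = 4.0
    min_magnitude_fraction: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.ic_interval_bounds
        if not 0 < lo < hi:
            raise ValueError("ic_interval_bounds must satisfy 0 < min < max")


@dataclass
class GaitEventSeries:
    """Time-ordered IC/FC events with foot labels and bout structure.

    ``events`` has columns time (s), kind ("IC"|"FC"), foot ("L"|"R"|
    "unknown") and magnitude (absolute CWT extremum, arbitrary units).
    ``bouts`` is a list of ``(start, stop)`` half-open index ranges into
    ``events`` delimiting continuous walking bouts.
    """

    events: pd.DataFrame
    bouts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.events.columns) != EVENT_COLUMNS:
            self.events = self.events.reindex(columns=EVENT_COLUMNS)
        t = self.events["time"].to_numpy(float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def ics(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "IC"]

    def fcs(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "FC"]

    def bout_events(self, bout: tuple[int, int]) -> pd.DataFrame:
        return self.events.iloc[bout[0] : bout[1]]

    def to_dict(self) -> dict:
        return {
            "events": self.events.to_dict(orient="records"),
            "bouts": [list(b) for b in self.bouts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitEventSeries":
        ev = pd.DataFrame(d["events"], columns=EVENT_COLUMNS)
        return cls(events=ev, bouts=[tuple(b) for b in d["bouts"]])


def _empty_series() -> GaitEventSeries:
    return GaitEventSeries(events=pd.DataFrame(columns=EVENT_COLUMNS), bouts=[])


def cwt_differentiate(x: np.ndarray, scale: float, wavelet: str = "gaus1") -> np.ndarray:
    """Smoothed differentiation of ``x`` via a single-scale CWT.

    Returns coefficients following the CWT sign convention for odd wavelets:
    the response to a rising slope is *negative*, so minima of the output
    mark maxima of the smoothed derivative.  The default "gaus1" path is
    computed directly as the negated Gaussian-derivative convolution; other
    wavelet families go through :func:`pywt.cwt` and are oriented to the
    same convention with a linear-ramp probe.
    """
    x = np.asarray(x, dtype=float)
    if wavelet == "gaus1":
        return -gaussian_filter1d(x, sigma=scale, order=1, mode="nearest")
    coef, _ = pywt.cwt(x, [scale], wavelet)
    out = np.real(coef[0])
    probe_len = max(int(12 * scale), 24)
    probe, _ = pywt.cwt(np.arange(probe_len, dtype=float), [scale], wavelet)
    orientation = float(np.real(probe[0][probe_len // 4 : -probe_len // 4]).mean())
    if abs(orientation) < 1e-12:
        raise ValueError(f"wavelet {wavelet!r} is symmetric and cannot act as a differentiator")
    if orientation > 0:
        out = -out
    return out


def _auto_scale(v: np.ndarray, sample_rate: float) -> float:
    """CWT scale (samples) from the dominant locomotor frequency of ``v``."""
    spectrum = np.abs(np.fft.rfft(v - v.mean()))
    freqs = np.fft.rfftfreq(len(v), d=1.0 / sample_rate)
    band = (freqs >= 0.4) & (freqs <= 4.0)
    if not band.any() or spectrum[band].max() == 0:
        return max(2.0, 0.05 * sample_rate)  # 50 ms fallback width
    f0 = freqs[band][np.argmax(spectrum[band])]
    return float(np.clip(sample_rate / (10.0 * f0), 2.0, sample_rate / 4.0))


def cwt_detect_events(
    recording: AccelerometerRecording, config: DetectorConfig | None = None
) -> GaitEventSeries:
    """Detect unfiltered IC/FC candidates from the vertical acceleration.

    Pipeline: mean-remove a_v, integrate (cumulative trapezoid), CWT
    differentiation → IC candidates at minima; second CWT differentiation →
    FC candidates at maxima.  Magnitudes (absolute extremum values) are kept
    for downstream tie-breaking; no foot labels are assigned here.

    A recording too short to hold a few steps, or a constant signal, yields
    an empty series (with a warning for the former).
    """
    config = config or DetectorConfig()
    fs = recording.sample_rate
    av = recording.av - recording.av.mean()

    min_duration = 4 * config.ic_interval_bounds[0]
    if recording.duration < min_duration:
        warnings.warn("recording too short for event detection; returning empty series", stacklevel=2)
        return _empty_series()
    if np.ptp(av) == 0:
        return _empty_series()

    v = cumulative_trapezoid(av, dx=1.0 / fs, initial=0.0)
    scale = _auto_scale(v, fs) if config.scale == "auto" else float(config.scale)

    d1 = cwt_differentiate(v, scale, config.wavelet)
    d2 = cwt_differentiate(d1, scale, config.wavelet)

    guard = int(np.ceil(config.edge_guard_scales * scale))

    def candidates(signal: np.ndarray) -> np.ndarray:
        idx, _ = find_peaks(signal)
        idx = idx[(idx >= guard) & (idx < len(av) - guard)]
        if len(idx) and config.min_magnitude_fraction > 0:
            mags = np.abs(signal[idx])
            idx = idx[mags >= config.min_magnitude_fraction * np.median(mags)]
        return idx

    ic_idx = candidates(-d1)
    fc_idx = candidates(d2)

    rows = [
        {"time": recording.start_time + i / fs, "kind": "IC", "foot": "unknown", "magnitude": abs(d1[i])}
        for i in ic_idx
    ] + [
        {"time": recording.start_time + i / fs, "kind": "FC", "foot": "unknown", "magnitude": abs(d2[i])}
        for i in fc_idx
    ]
    if not rows:
        return _empty_series()
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("time", kind="stable")
    # an IC and FC candidate may coincide on the same sample; nudge is not
    # needed because sorting keeps both and downstream logic is kind-aware,
    # but strict monotonicity requires dropping exact duplicates of a kind
    ev = ev.drop_duplicates(subset=["time", "kind"]).reset_index(drop=True)
    ev = _break_time_ties(ev)
    return GaitEventSeries(events=ev, bouts=[(0, len(ev))])


def _break_time_ties(ev: pd.DataFrame) -> pd.DataFrame:
    """Offset exact time ties (IC and FC on one sample) by a nanosecond."""
    t = ev["time"].to_numpy(float).copy()
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1e-9
    ev = ev.copy()
    ev["time"] = t
    return ev


def filter_spurious_ics(
    series: GaitEventSeries, bounds: tuple[float, float] = (0.25, 2.25)
) -> GaitEventSeries:
    """Reject spurious ICs and delimit walking bouts.

    While any two consecutive ICs are closer than the lower bound, the one
    with the smaller detection magnitude is discarded (the weaker extremum
    is taken to be the artefact).  Remaining IC gaps longer than the upper
    bound split the series into bouts — no step is formed across such a gap.
    FCs are retained only when they fall inside a bout's IC span.
    """
    min_s, max_s = bounds
    ics = series.ics().sort_values("time").reset_index(drop=True)
    fcs = series.fcs()
    if ics.empty:
        return _empty_series()

    t = list(ics["time"].to_numpy(float))
    m = list(ics["magnitude"].to_numpy(float))
    changed = True
    while changed and len(t) > 1:
        changed = False
        for i in range(len(t) - 1):
            if t[i + 1] - t[i] < min_s:
                drop = i if m[i] <= m[i + 1] else i + 1
                del t[drop], m[drop]
                changed = True
                break

    # split into bouts at gaps exceeding the upper bound
    bout_ic_groups: list[list[int]] = [[0]]
    for i in range(1, len(t)):
        if t[i] - t[i - 1] > max_s:
            bout_ic_groups.append([i])
        else:
            bout_ic_groups[-1].append(i)

    fc_t = fcs["time"].to_numpy(float)
    fc_m = fcs["magnitude"].to_numpy(float)
    rows, bouts = [], []
    for group in bout_ic_groups:
        start = len(rows)
        lo, hi = t[group[0]], t[group[-1]]
        in_bout = (fc_t >= lo) & (fc_t <= hi)
        merged = sorted(
            [{"time": t[i], "kind": "IC", "foot": "unknown", "magnitude": m[i]} for i in group]
            + [
                {"time": ft, "kind": "FC", "foot": "unknown", "magnitude": fm}
                for ft, fm in zip(fc_t[in_bout], fc_m[in_bout])
            ],
            key=lambda r: (r["time"], r["kind"] == "IC"),
        )
        rows.extend(merged)
        bouts.append((start, len(rows)))

    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    ev = _break_time_ties(ev)
    return GaitEventSeries(events=ev, bouts=bouts)


def assign_feet(series: GaitEventSeries, first_foot: str | list[str] | None) -> GaitEventSeries:
    """Label events left/right by alternation from a known first foot.

    ``first_foot`` may be a single label (applied to the first IC of every
    bout) or one label per bout.  ICs alternate within a bout; each FC takes
    the foot contralateral to the nearest preceding IC, which places FC_X
    just after IC of the opposite foot so stance_X = FC_X − IC_X.  With no
    first-foot information every label is "unknown" and left/right splits
    downstream are disabled.
    """
    ev = series.events.copy()
    if first_foot is None:
        ev["foot"] = "unknown"
        return GaitEventSeries(events=ev, bouts=list(series.bouts))

    if isinstance(first_foot, str):
        per_bout = [first_foot] * len(series.bouts)
    else:
        if len(first_foot) != len(series.bouts):
            raise ValueError("need one first_foot per bout")
        per_bout = list(first_foot)

    kinds = ev["kind"].to_numpy()
    feet = np.array(["unknown"] * len(ev), dtype=object)
    for (start, stop), ff in zip(series.bouts, per_bout):
        if ff not in ("L", "R"):
            raise ValueError(f"first_foot must be 'L' or 'R', got {ff!r}")
        current = None
        for i in range(start, stop):
            if kinds[i] == "IC":
                current = ff if current is None else _OPPOSITE[current]
                feet[i] = current
            elif current is not None:
                feet[i] = _OPPOSITE[current]
    ev["foot"] = feet
    return GaitEventSeries(events=ev, bouts=list(series.bouts))


def count_steps(series: GaitEventSeries) -> int:
    """Total number of retained ICs over all bouts."""
    return int((series.events["kind"] == "IC").sum()) if len(series.events) else 0


def detect(
    recording: AccelerometerRecording,
    config: DetectorConfig | None = None,
    first_foot: str | None = None,
) -> GaitEventSeries:
    """Full detection pipeline: candidates → spurious-IC filter → feet."""
    config = config or DetectorConfig()
    series = cwt_detect_events(recording, config)
    series = filter_spurious_ics(series, config.ic_interval_bounds)
    ff = first_foot if first_foot is not None else recording.meta.get("first_foot")
    return assign_feet(series, ff)
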