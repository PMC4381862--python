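"""Synthetic lumbar vertical-acceleration walks with full ground truth.

The generator emulates the signal a lumbar-worn accelerometer sees during
continuous level walking, following the same inverted-pendulum geometry the
analysis pipeline assumes.  Per step k, a duration T_k and step length SL_k
are drawn (truncated normal, with a configurable left/right offset for
asymmetry); the chord geometry is inverted to the CoM rise
h_k = l − √(l² − SL_k²/4), and the vertical CoM displacement over the step
window is a raised-cosine arc of height h_k — C¹-continuous across steps,
lowest at each IC and peaking mid-step, like the pendulum vault.  The
vertical acceleration is the analytic second derivative of that
displacement, plus gravity, sensor noise, optional spike artefacts, a slow
linear drift term, and optional 16-bit ±8 g quantisation.

True IC times are the arc boundaries; true FC times are placed at a
configurable stance fraction of each stride (stance ≈ 0.62 × stride in
healthy adults).  The returned ground truth carries event times, the true
per-step table and its summary, so every pipeline stage can be scored
without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
import yaml

from . import characteristics
from .signal_io import G, STEP_COLUMNS, AccelerometerRecording, write_recording
from .spatiotemporal import h_from_length

__all__ = ["SimulationConfig", "CohortConfig", "GroundTruth", "generate_walk",
           "simulate_two_systems", "write_fixture"]


@dataclass
class SimulationConfig:
    """Ground-truth walk parameters.

    Defaults describe a younger healthy adult walking at a self-selected
    pace: ~0.535 s steps with ~0.02 s stride-to-stride SD, a small left/right
    offset, ~79 cm steps, a lumbar sensor 0.91 m above ground, stance
    occupying 0.62 of the stride, sampled at 100 Hz.  ``seed`` is mandatory:
    every stochastic field draws from one generator seeded with it.
    """

    n_steps: int = 238
    mean_step_time: float = 0.535          # s
    step_time_sd: float = 0.019            # s, stride-to-stride
    step_time_asymmetry: float = 0.008     # s, |mean_L − mean_R|
    step_length_cm: float = 78.6           # cm
    step_length_sd_cm: float = 4.9         # cm
    sensor_height: float = 0.91            # m (pendulum length l)
    stance_fraction: float = 0.62          # stance / stride
    noise_sd: float = 0.2                  # m/s², white sensor noise
    spike_rate: float = 0.0                # artefacts per step
    spike_amplitude: float = 5.0           # m/s²
    drift_slope: float = 0.0               # m/s³, slow additive bias
    quantize: bool = False                 # 16-bit over ±8 g
    sample_rate: float = 100.0             # Hz
    pad_s: float = 2.0                     # quiet lead-in/out, s
    first_foot: str = "L"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.25 < self.mean_step_time < 2.25:
            raise ValueError("mean_step_time must lie in the physiological window (0.25, 2.25) s")
        if self.step_length_cm / 100.0 >= 2.0 * self.sensor_height:
            raise ValueError("step length must be below 2 × sensor height (pendulum geometry)")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.first_foot not in ("L", "R"):
            raise ValueError("first_foot must be 'L' or 'R'")
        stochastic = self.step_time_sd or self.step_length_sd_cm or self.noise_sd or self.spike_rate
        if stochastic and self.seed is None:
            raise ValueError("seed is required when any stochastic field is non-zero")


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated recording."""

    ic_times: np.ndarray          # n_steps + 1 boundaries
    ic_feet: np.ndarray
    fc_times: np.ndarray
    fc_feet: np.ndarray
    h: np.ndarray                 # per-step CoM rise, m
    step_table: pd.DataFrame
    summary: pd.DataFrame
    config: SimulationConfig

    @property
    def n_steps(self) -> int:
        return len(self.step_table)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int,
               lo: float = -np.inf, hi: float = np.inf) -> np.ndarray:
    """Normal draws truncated at ±3 SD (and optional hard bounds), by rejection."""
    if sd == 0:
        return np.full(size, mean)
    lo = max(lo, mean - 3 * sd)
    hi = min(hi, mean + 3 * sd)
    out = np.empty(size)
    todo = np.arange(size)
    while len(todo):
        draw = rng.normal(mean, sd, size=len(todo))
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _draw_steps(config: SimulationConfig, rng: np.random.Generator):
    """Per-step durations, feet, lengths and CoM rises for one walk."""
    n = config.n_steps
    feet = np.array([(config.first_foot if k % 2 == 0 else
                      ("R" if config.first_foot == "L" else "L")) for k in range(n)], dtype=object)
    T = np.empty(n)
    for side in ("L", "R"):
        mask = feet == side
        mu = config.mean_step_time + (1 if side == "L" else -1) * config.step_time_asymmetry / 2.0
        T[mask] = _truncnorm(rng, mu, config.step_time_sd, int(mask.sum()), lo=0.25, hi=2.25)
    l = config.sensor_height
    sl_hi = (2.0 * l - 1e-6) * 100.0
    SL = _truncnorm(rng, config.step_length_cm, config.step_length_sd_cm, n, lo=1e-3, hi=sl_hi)
    h = h_from_length(l, SL / 100.0)
    return feet, T, SL, np.atleast_1d(h)


def _truth_table(feet, T, SL, config: SimulationConfig) -> pd.DataFrame:
    n = len(T)
    stride = np.full(n, np.nan)
    stride[: n - 1] = T[: n - 1] + T[1:]
    stance = config.stance_fraction * stride
    swing = stride - stance
    table = pd.DataFrame(
        {
            "bout_id": 0.0,
            "pass_id": np.nan,
            "on_walkway": np.nan,
            "foot": feet,
            "step_time": T,
            "stride_time": stride,
            "stance_time": stance,
            "swing_time": swing,
            "step_length": SL,
            "step_velocity": SL / T,
        },
        columns=STEP_COLUMNS,
    )
    return table


def generate_walk(config: SimulationConfig) -> tuple[AccelerometerRecording, GroundTruth]:
    """Generate one continuous walk and its ground truth.

    Identical configs (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    feet, T, SL, h = _draw_steps(config, rng)
    n = config.n_steps
    fs = config.sample_rate

    ic_times = config.pad_s + np.concatenate([[0.0], np.cumsum(T)])
    total = ic_times[-1] + config.pad_s if n else 2 * config.pad_s
    n_samples = int(round(total * fs)) + 1
    t = np.arange(n_samples) / fs

    av = np.zeros(n_samples)
    for k in range(n):
        i0 = int(np.ceil(ic_times[k] * fs))
        i1 = int(np.floor(ic_times[k + 1] * fs))
        if i1 < i0:
            continue
        w = 2.0 * np.pi / T[k]
        av[i0 : i1 + 1] = (h[k] / 2.0) * w * w * np.cos(w * (t[i0 : i1 + 1] - ic_times[k]))

    av = av + G
    lateral = np.zeros((n_samples, 2))
    if config.noise_sd:
        av = av + rng.normal(0.0, config.noise_sd, n_samples)
        lateral = rng.normal(0.0, config.noise_sd, (n_samples, 2))
    if config.drift_slope:
        av = av + config.drift_slope * (t - t.mean())
    if config.spike_rate and n:
        n_spikes = rng.poisson(config.spike_rate * n)
        if n_spikes:
            idx = rng.integers(int(ic_times[0] * fs), int(ic_times[-1] * fs), n_spikes)
            av[idx] += config.spike_amplitude * rng.choice([-1.0, 1.0], n_spikes)
    samples = np.column_stack([lateral[:, 0], lateral[:, 1], av])
    if config.quantize:
        lsb = 16.0 * G / 2**16
        samples = np.clip(np.round(samples / lsb) * lsb, -8 * G, 8 * G)

    recording = AccelerometerRecording(
        samples=samples,
        sample_rate=fs,
        vertical_axis=2,
        sensor_height=config.sensor_height,
        meta={"first_foot": config.first_foot, "synthetic": True},
    )

    table = _truth_table(feet, T, SL, config)
    stride = table["stride_time"].to_numpy(float)
    fc_times = ic_times[: max(n - 1, 0)] + config.stance_fraction * stride[: max(n - 1, 0)]
    fc_feet = feet[: max(n - 1, 0)].copy()
    if n:
        ic_feet = np.append(feet, "L" if feet[-1] == "R" else "R")
    else:
        ic_feet = np.array([], dtype=object)
    truth = GroundTruth(
        ic_times=ic_times if n else np.array([]),
        ic_feet=ic_feet,
        fc_times=fc_times,
        fc_feet=fc_feet,
        h=h,
        step_table=table,
        summary=characteristics.summarize(table),
        config=config,
    )
    return recording, truth


@dataclass
class CohortConfig:
    """Between-subject spread for simulated cohorts.

    SDs describe how subject-level walk parameters vary across a healthy
    cohort: mean step time ~0.04 s, mean step length ~5.8 cm, with
    subject-specific stride-to-stride variability and asymmetry drawn
    around the base config's values.
    """

    n_subjects: int = 20
    mean_step_time_sd: float = 0.038       # s
    mean_step_length_sd: float = 5.8       # cm
    step_time_sd_spread: float = 0.005     # s
    asymmetry_spread: float = 0.007        # s
    n_passes: int = 7


def simulate_two_systems(
    config: SimulationConfig,
    noise_ref: float = 0.01,
    noise_test: float = 0.01,
    misallocation: int = 0,
    cohort: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired per-subject summaries from two noisy views of one cohort.

    Each subject's true step table is observed by two "systems", each adding
    independent per-step measurement noise (SD = ``noise_*`` as a fraction
    of the characteristic's subject mean).  ``misallocation`` injects the
    step-count segmentation failure of walkway comparisons: on every other
    pass, the test system's left/right labels are shifted by that many
    steps, so a ±1 miscount flips the labels of the whole pass.  Returns
    (reference, test) DataFrames of flattened summaries indexed by subject.
    """
    cohort = cohort or CohortConfig()
    if cohort.n_subjects < 3:
        raise ValueError("need a cohort of at least 3 subjects")
    rng = np.random.default_rng(config.seed)
    ref_rows, test_rows = {}, {}
    for s in range(cohort.n_subjects):
        sub = replace(
            config,
            mean_step_time=float(np.clip(rng.normal(config.mean_step_time, cohort.mean_step_time_sd), 0.3, 2.0)),
            step_length_cm=float(np.clip(rng.normal(config.step_length_cm, cohort.mean_step_length_sd),
                                         10.0, 2.0 * config.sensor_height * 100.0 - 1.0)),
            step_time_sd=float(abs(rng.normal(config.step_time_sd, cohort.step_time_sd_spread))),
            step_time_asymmetry=float(abs(rng.normal(config.step_time_asymmetry, cohort.asymmetry_spread))),
            seed=int(rng.integers(2**31)),
        )
        feet, T, SL, _ = _draw_steps(sub, np.random.default_rng(sub.seed))
        truth = _truth_table(feet, T, SL, sub)
        ref_rows[f"S{s:03d}"] = characteristics.summary_to_row(
            characteristics.summarize(_observe(truth, noise_ref, rng))
        )
        observed = _observe(truth, noise_test, rng)
        if misallocation:
            observed = _misallocate(observed, misallocation, cohort.n_passes)
        test_rows[f"S{s:03d}"] = characteristics.summary_to_row(characteristics.summarize(observed))
    return pd.DataFrame(ref_rows).T, pd.DataFrame(test_rows).T


def _observe(truth: pd.DataFrame, noise_frac: float, rng: np.random.Generator) -> pd.DataFrame:
    """Truth plus independent per-step measurement noise, relative to each mean."""
    obs = truth.copy()
    if noise_frac:
        for char in characteristics.CHARACTERISTICS:
            col = obs[char].to_numpy(float)
            scale = noise_frac * np.nanmean(col)
            obs[char] = col + rng.normal(0.0, abs(scale), len(col))
    return obs


def _misallocate(table: pd.DataFrame, shift: int, n_passes: int) -> pd.DataFrame:
    """Shift left/right labels by ``shift`` steps on every other pass.

    Mirrors the failure mode of segmenting a continuous step sequence with
    an off-by-one external step count: a one-step shift exchanges every L
    and R label in the affected pass, leaving means untouched but scrambling
    asymmetry.
    """
    out = table.copy().reset_index(drop=True)
    feet = out["foot"].to_numpy(object).copy()
    bounds = np.linspace(0, len(out), n_passes + 1).astype(int)
    flip = {"L": "R", "R": "L"}
    for p in range(n_passes):
        if p % 2 == 0:
            continue
        lo, hi = bounds[p], bounds[p + 1]
        if abs(shift) % 2 == 1:
            feet[lo:hi] = [flip.get(f, f) for f in feet[lo:hi]]
    out["foot"] = feet
    return out


def write_fixture(config: SimulationConfig, directory: str | Path) -> dict[str, Path]:
    """Write recording.csv, meta.yaml and truth.json for one simulated walk.

    Regeneration from the same (config, seed) is deterministic, so fixtures
    never need to be stored — only their configs do.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recording, truth = generate_walk(config)
    rec_path = directory / "recording.csv"
    write_recording(recording, rec_path, sidecar=False)
    meta_path = directory / "meta.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(
            {
                "sample_rate_hz": recording.sample_rate,
                "units": "m/s2",
                "vertical_axis": recording.vertical_axis,
                "sensor_height_m": recording.sensor_height,
                "first_foot": config.first_foot,
                "synthetic": True,
            },
            fh, sort_keys=False,
        )
    truth_path = directory / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "ic_times": truth.ic_times.tolist(),
                "ic_feet": truth.ic_feet.tolist(),
                "fc_times": truth.fc_times.tolist(),
                "fc_feet": truth.fc_feet.tolist(),
                "h_m": truth.h.tolist(),
                "step_table": truth.step_table.where(pd.notna(truth.step_table), None).to_dict(orient="records"),
            },
            fh,
        )
    return {"recording": rec_path, "meta": meta_path, "truth": truth_path}
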