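import numpy as np
import pandas as pd
import pytest

from gaitbwm import (
    AccelerometerRecording,
    GaitEventSeries,
    SimulationConfig,
    detect,
    generate_walk,
)
from gaitbwm.event_detection import EVENT_COLUMNS
from gaitbwm.signal_io import G


def make_series(ic_times, fc_times=(), ic_feet=None, fc_feet=None, ic_mags=None):
    """Hand-built event series (single bout) for oracle tests."""
    rows = []
    ic_mags = ic_mags if ic_mags is not None else [1.0] * len(ic_times)
    ic_feet = ic_feet if ic_feet is not None else ["unknown"] * len(ic_times)
    fc_feet = fc_feet if fc_feet is not None else ["unknown"] * len(fc_times)
    for t, f, m in zip(ic_times, ic_feet, ic_mags):
        rows.append({"time": t, "kind": "IC", "foot": f, "magnitude": m})
    for t, f in zip(fc_times, fc_feet):
        rows.append({"time": t, "kind": "FC", "foot": f, "magnitude": 1.0})
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("time").reset_index(drop=True)
    return GaitEventSeries(events=ev, bouts=[(0, len(ev))])


def sinusoid_recording(freq=2.0, duration=30.0, fs=100.0, amplitude=1.0, height=None):
    t = np.arange(int(duration * fs) + 1) / fs
    av = amplitude * np.sin(2 * np.pi * freq * t) + G
    samples = np.column_stack([np.zeros_like(t), np.zeros_like(t), av])
    return AccelerometerRecording(samples=samples, sample_rate=fs, sensor_height=height)


@pytest.fixture(scope="session")
def quiet_walk():
    """Noiseless deterministic walk: exact geometry, no stochastic terms."""
    cfg = SimulationConfig(
        n_steps=40, step_time_sd=0.0, step_time_asymmetry=0.0,
        step_length_sd_cm=0.0, noise_sd=0.0, seed=0,
    )
    rec, truth = generate_walk(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noisy_walk():
    cfg = SimulationConfig(n_steps=120, seed=42)
    rec, truth = generate_walk(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def detected_noisy_walk(noisy_walk):
    cfg, rec, truth = noisy_walk
    return cfg, rec, truth, detect(rec)
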