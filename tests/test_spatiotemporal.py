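import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitbwm import (
    AccelerometerRecording,
    compute_temporal_params,
    detect,
    estimate_vertical_excursion,
    extract_step_table,
    h_from_length,
    segment_passes,
    step_length,
    step_velocity,
    validate_step_table,
)
from gaitbwm.signal_io import G
from conftest import make_series


def test_gait_cycle_decomposition_on_constructed_events():
    """Step/stride/stance/swing from an ideal alternating IC/FC sequence."""
    series = make_series(
        [0.0, 0.5, 1.0, 1.5],
        fc_times=[0.12, 0.62, 1.12],
        ic_feet=["L", "R", "L", "R"],
        fc_feet=["R", "L", "R"],
    )
    table = compute_temporal_params(series)
    assert np.allclose(table["step_time"], 0.5)
    assert table.loc[0, "stride_time"] == pytest.approx(1.0)
    assert table.loc[0, "stance_time"] == pytest.approx(0.62)
    assert table.loc[0, "swing_time"] == pytest.approx(0.38)
    assert table.loc[0, "stance_time"] + table.loc[0, "swing_time"] == pytest.approx(
        table.loc[0, "stride_time"]
    )
    validate_step_table(table)


def test_two_ics_give_one_step_and_nothing_else():
    table = compute_temporal_params(make_series([0.0, 0.55], ic_feet=["L", "R"]))
    assert len(table) == 1
    assert table.loc[0, "step_time"] == pytest.approx(0.55)
    assert np.isnan(table.loc[0, "stride_time"])
    assert np.isnan(table.loc[0, "stance_time"])


def test_unlabelled_feet_suppress_stance_swing_only():
    series = make_series([0.0, 0.5, 1.0, 1.5], fc_times=[0.62, 1.12])
    table = compute_temporal_params(series)
    assert np.isfinite(table["step_time"]).all()
    assert table["stance_time"].isna().all()
    assert table["swing_time"].isna().all()


def test_periodic_walk_strides_recovered(quiet_walk):
    cfg, rec, truth = quiet_walk
    table = compute_temporal_params(detect(rec))
    # first/last strides border the quiet pads, where the smoothed boundary
    # extremum is pulled inward; interior strides recover the true period
    strides = table["stride_time"].dropna().iloc[1:-1]
    assert np.allclose(strides, 2 * cfg.mean_step_time, atol=1.0 / rec.sample_rate)


def test_zero_acceleration_gives_zero_excursion():
    n = 500
    rec = AccelerometerRecording(
        np.column_stack([np.zeros(n), np.zeros(n), np.full(n, G)]), sample_rate=100.0
    )
    series = make_series([1.0, 1.5, 2.0])
    h = estimate_vertical_excursion(rec, series)
    assert np.allclose(h, 0.0, atol=1e-12)


def test_sinusoid_excursion_matches_closed_form():
    """a_v = −Aω² sin(ωt) double-integrates to A·sin(ωt): range 2A per period."""
    # high sampling rate so trapezoid error stays below the 1e-3 tolerance
    A, freq, fs = 0.012, 2.0, 400.0
    t = np.arange(int(10 * fs) + 1) / fs
    w = 2 * np.pi * freq
    av = -A * w * w * np.sin(w * t) + G
    rec = AccelerometerRecording(np.column_stack([0 * t, 0 * t, av]), sample_rate=fs)
    series = make_series([2.0, 2.5, 3.0, 3.5])  # full-period windows
    h = estimate_vertical_excursion(rec, series)
    assert np.allclose(h, 2 * A, rtol=1e-3)


def test_short_window_gives_absent_excursion():
    n = 500
    rec = AccelerometerRecording(
        np.column_stack([np.zeros(n), np.zeros(n), np.full(n, G)]), sample_rate=100.0
    )
    series = make_series([1.0, 1.01, 2.0])
    h = estimate_vertical_excursion(rec, series)
    assert np.isnan(h[0]) and np.isfinite(h[1])


def test_step_length_closed_form_values():
    assert step_length(1.0, 0.0) == pytest.approx(0.0)
    assert step_length(0.95, 0.03) == pytest.approx(47.371, abs=5e-4)
    assert step_length(0.9, 0.9) == pytest.approx(180.0)  # h = l: geometric maximum 2l


def test_step_length_invalid_excursions_flagged():
    assert np.isnan(step_length(0.9, -0.01))
    assert np.isnan(step_length(0.9, 0.95))
    with pytest.raises(ValueError):
        step_length(-1.0, 0.02)
    with pytest.raises(ValueError):
        step_length(1.0, 0.02, correction=-0.5)


@settings(derandomize=True, max_examples=100)
@given(
    l=st.floats(0.5, 1.3),
    sl=st.floats(0.05, 0.95),
)
def test_pendulum_inverse_consistency(l, sl):
    """step_length(l, h_from_length(l, SL)) recovers SL to 1e−12."""
    sl_m = sl * l  # keep chord feasible
    h = h_from_length(l, sl_m)
    assert step_length(l, h) == pytest.approx(sl_m * 100.0, abs=1e-10)


def test_step_length_monotone_in_h():
    l = 0.95
    hs = np.linspace(0.0, l, 200)
    sls = step_length(l, hs)
    assert np.all(np.diff(sls) > 0)


def test_step_velocity_ratio_and_absence():
    assert step_velocity(75.0, 0.5) == pytest.approx(150.0)
    assert np.isnan(step_velocity(np.nan, 0.5))
    assert np.isnan(step_velocity(75.0, 0.0))


def test_segment_passes_assigns_counts_in_order():
    table = pd.DataFrame({"foot": ["L", "R"] * 5, "step_time": [0.5] * 10, "bout_id": 0.0})
    out = segment_passes(table, [4, 6], [True, False])
    assert list(out["pass_id"][:4]) == [1.0] * 4
    assert list(out["pass_id"][4:]) == [2.0] * 6
    assert list(out["on_walkway"][:4]) == [True] * 4


def test_segment_passes_surplus_goes_to_trailing_segment():
    table = pd.DataFrame({"foot": ["L", "R"] * 5, "step_time": [0.5] * 10, "bout_id": 0.0})
    out = segment_passes(table, [4, 3], [True, False])
    assert list(out["pass_id"][7:]) == [3.0] * 3
    assert list(out["on_walkway"][7:]) == [False] * 3


def test_segment_passes_negative_count_rejected():
    table = pd.DataFrame({"foot": ["L"], "step_time": [0.5], "bout_id": 0.0})
    with pytest.raises(ValueError):
        segment_passes(table, [-1])


def test_end_to_end_recovery_zero_noise(quiet_walk):
    """Noiseless pipeline: mean step time within 5 ms, length within 5%."""
    cfg, rec, truth = quiet_walk
    table = extract_step_table(rec, detect(rec))
    assert abs(table["step_time"].mean() - truth.step_table["step_time"].mean()) < 0.005
    rel = abs(table["step_length"].mean() - truth.step_table["step_length"].mean())
    assert rel / truth.step_table["step_length"].mean() < 0.05
    validate_step_table(table)


def test_simulated_excursion_recovered(quiet_walk):
    cfg, rec, truth = quiet_walk
    series = detect(rec)
    h = estimate_vertical_excursion(rec, series)
    h = h[np.isfinite(h)]
    assert abs(np.mean(h) - np.mean(truth.h)) / np.mean(truth.h) < 0.05
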