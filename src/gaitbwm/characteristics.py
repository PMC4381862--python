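"""Mean, variability and asymmetry summaries of per-step gait data.

Six characteristics are summarised: step time, stride time, stance time,
swing time, step length and step velocity.  For each, means and sample SDs
are computed for left and right steps separately and then combined:

* combined mean — mean over all steps (not the mean of the two foot means);
* asymmetry — |mean_left − mean_right|;
* combined SD — √((var_left + var_right) / 2), the square root of the mean
  of the per-foot variances.  Pooling variances this way keeps a systematic
  left/right offset from inflating the variability estimate, which a naive
  SD over all steps would conflate with true stride-to-stride variability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CHARACTERISTICS", "STATISTICS", "asymmetry", "combined_sd", "summarize",
           "summary_to_row", "write_summary"]

CHARACTERISTICS = ["step_time", "stride_time", "stance_time", "swing_time", "step_length", "step_velocity"]
STATISTICS = ["mean_L", "mean_R", "mean", "sd_L", "sd_R", "sd", "asymmetry"]


def asymmetry(mean_left: float, mean_right: float) -> float:
    """Absolute left/right difference of per-foot means; NaN if either is absent."""
    if mean_left is None or mean_right is None:
        return float("nan")
    return float(abs(mean_left - mean_right))


def combined_sd(var_left: float, var_right: float) -> float:
    """√ of the mean of the left and right step variances."""
    if var_left < 0 or var_right < 0:
        raise ValueError("variances must be non-negative")
    return float(np.sqrt((var_left + var_right) / 2.0))


def _foot_stats(values: np.ndarray) -> tuple[float, float]:
    """(mean, sample SD) of finite values; SD absent below 2 observations."""
    v = values[np.isfinite(values)]
    mean = float(v.mean()) if len(v) else float("nan")
    sd = float(v.std(ddof=1)) if len(v) >= 2 else float("nan")
    return mean, sd


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-characteristic summary of a step table.

    Returns a DataFrame indexed by characteristic with columns mean_L,
    mean_R, mean, sd_L, sd_R, sd and asymmetry.  Without foot labels only
    the combined mean and a plain SD over all steps are emitted.
    """
    labelled = table["foot"].isin(["L", "R"]) if "foot" in table.columns else pd.Series(False, index=table.index)
    out = {}
    for char in CHARACTERISTICS:
        if char in table.columns:
            col = table[char].to_numpy(float)
        else:
            col = np.full(len(table), np.nan)
        mean_all, sd_all = _foot_stats(col)
        if labelled.any():
            ml, sl = _foot_stats(col[(table["foot"] == "L").to_numpy()])
            mr, sr = _foot_stats(col[(table["foot"] == "R").to_numpy()])
            sd = combined_sd(sl**2, sr**2) if np.isfinite(sl) and np.isfinite(sr) else float("nan")
            asym = asymmetry(ml, mr) if np.isfinite(ml) and np.isfinite(mr) else float("nan")
        else:
            ml = mr = asym = float("nan")
            sl = sr = float("nan")
            sd = sd_all
        out[char] = {
            "mean_L": ml, "mean_R": mr, "mean": mean_all,
            "sd_L": sl, "sd_R": sr, "sd": sd, "asymmetry": asym,
        }
    return pd.DataFrame(out).T.reindex(columns=STATISTICS)


def summary_to_row(summary: pd.DataFrame) -> pd.Series:
    """Flatten a summary into one row keyed '<characteristic>_<mean|sd|asymmetry>'.

    This is the per-subject vector fed to the system-agreement analysis.
    """
    row = {}
    for char in summary.index:
        for stat in ("mean", "sd", "asymmetry"):
            row[f"{char}_{stat}"] = summary.loc[char, stat]
    return pd.Series(row)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({c: {s: _jsonable(summary.loc[c, s]) for s in summary.columns} for c in summary.index}, fh, indent=2)


def _jsonable(x):
    x = float(x)
    return None if np.isnan(x) else x
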