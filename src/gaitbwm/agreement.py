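"""System-agreement statistics for method-comparison studies.

Compares a body-worn monitor (BWM) against a reference system (e.g. an
instrumented walkway) per gait characteristic across subjects:

* ICC(2,k) — two-way random-effects, average-measures, absolute-agreement
  intraclass correlation (Shrout–Fleiss), computed from the two-way ANOVA
  mean squares: (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n).
* Bland–Altman mean difference and 95% limits of agreement
  (± 1.96 · sample SD of the paired differences).
* Relative LoA% — the LoA half-width as a percentage of the grand mean of
  the two system means.
* Pearson r and Spearman ρ.
* Qualitative rating bands: excellent / good / moderate / poor for both the
  ICC (> 0.900 / ≥ 0.750 / ≥ 0.500 / below) and LoA%
  ([0, 5) / [5, 10) / [10, 50) / ≥ 50).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "icc_2k",
    "bland_altman",
    "loa_percent",
    "rate_agreement",
    "correlations",
    "temporal_discrepancy",
    "compare_systems",
    "AgreementReport",
]


def icc_2k(measurements: np.ndarray) -> float:
    """ICC(2,k): two-way random effects, average measures, absolute agreement.

    ``measurements`` is a subjects × raters matrix with no missing cells
    (here typically n subjects × 2 systems).  Fewer than 3 subjects leaves
    the coefficient undefined (NaN with a warning); a matrix with zero total
    variance — identical constant columns — is perfect agreement, 1.0.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects × raters matrix with ≥ 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    if n < 3:
        warnings.warn("ICC undefined below 3 subjects", stacklevel=2)
        return float("nan")

    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total < 1e-300:
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n))


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mean difference (y − x) and 95% LoA half-width (1.96 · SD, ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    return float(d.mean()), float(1.96 * d.std(ddof=1))


def loa_percent(loa_halfwidth: float, mean_ref: float, mean_test: float) -> float:
    """LoA half-width as a percentage of the grand mean of the two system means."""
    grand = (mean_ref + mean_test) / 2.0
    if grand == 0:
        return float("nan")
    return float(100.0 * loa_halfwidth / grand)


def rate_agreement(icc: float, loa_pct: float) -> tuple[str, str]:
    """Qualitative bands for an ICC and a relative LoA%.

    ICC: excellent strictly above 0.900, good from 0.750, moderate from
    0.500, else poor.  LoA%: excellent below 5, good below 10, moderate
    below 50, else poor.  NaN inputs rate as "undefined".
    """
    if np.isnan(icc):
        icc_rating = "undefined"
    elif icc > 0.900:
        icc_rating = "excellent"
    elif icc >= 0.750:
        icc_rating = "good"
    elif icc >= 0.500:
        icc_rating = "moderate"
    else:
        icc_rating = "poor"

    if np.isnan(loa_pct):
        loa_rating = "undefined"
    elif loa_pct < 5.0:
        loa_rating = "excellent"
    elif loa_pct < 10.0:
        loa_rating = "good"
    elif loa_pct < 50.0:
        loa_rating = "moderate"
    else:
        loa_rating = "poor"
    return icc_rating, loa_rating


def correlations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Pearson r, Spearman ρ); NaN when either sample has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need paired samples of equal length ≥ 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return float(r), float(rho)


def temporal_discrepancy(spatial_accuracy_cm: float, step_velocity_cm_s: float) -> float:
    """Timing uncertainty (s) implied by a spatial resolution at a stepping speed.

    A pressure walkway that resolves contact position to d centimetres
    blurs event timing by d / v seconds for a subject moving at v cm/s —
    e.g. 1.27 cm at 142 cm/s is ≈ 0.009 s, at the scale of the temporal
    disagreements seen between walkway and accelerometer.
    """
    if step_velocity_cm_s <= 0:
        raise ValueError("step velocity must be positive")
    return float(spatial_accuracy_cm / step_velocity_cm_s)


REPORT_COLUMNS = [
    "icc", "pearson_r", "spearman_rho", "mean_diff",
    "loa_halfwidth", "loa_percent", "icc_rating", "loa_rating",
    "mean_ref", "sd_ref", "mean_test", "sd_test", "n",
]


@dataclass
class AgreementReport:
    """Per-characteristic agreement table (rows: characteristic_statistic)."""

    table: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {idx: {c: _jsonable(v) for c, v in row.items()} for idx, row in self.table.iterrows()},
                fh, indent=2,
            )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="characteristic")


def _jsonable(v):
    if isinstance(v, str):
        return v
    v = float(v)
    return None if np.isnan(v) else v


def compare_systems(ref: pd.DataFrame, test: pd.DataFrame) -> AgreementReport:
    """Full agreement protocol between two per-subject summary tables.

    ``ref`` and ``test`` are DataFrames indexed by subject id with matching
    numeric columns (one per characteristic/statistic).  Only the subject
    intersection is analysed; a mismatch is logged as a warning.
    """
    common = ref.index.intersection(test.index)
    if len(common) < len(ref.index) or len(common) < len(test.index):
        warnings.warn(
            f"subject mismatch: analysing {len(common)} common subjects", stacklevel=2
        )
    if len(common) < 3:
        raise ValueError("need at least 3 matched subjects")
    ref = ref.loc[common]
    test = test.loc[common]

    rows = {}
    for col in ref.columns:
        if col not in test.columns:
            continue
        x = ref[col].to_numpy(float)
        y = test[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            continue
        icc = icc_2k(np.column_stack([x, y]))
        r, rho = correlations(x, y)
        mean_diff, loa = bland_altman(x, y)
        pct = loa_percent(loa, x.mean(), y.mean())
        icc_rating, loa_rating = rate_agreement(icc, pct)
        rows[col] = {
            "icc": icc, "pearson_r": r, "spearman_rho": rho,
            "mean_diff": mean_diff, "loa_halfwidth": loa, "loa_percent": pct,
            "icc_rating": icc_rating, "loa_rating": loa_rating,
            "mean_ref": x.mean(), "sd_ref": x.std(ddof=1),
            "mean_test": y.mean(), "sd_test": y.std(ddof=1), "n": len(x),
        }
    return AgreementReport(table=pd.DataFrame(rows).T.reindex(columns=REPORT_COLUMNS))
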