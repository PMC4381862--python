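import numpy as np
import pandas as pd
import pytest

from gaitbwm import (
    CohortConfig,
    SimulationConfig,
    bland_altman,
    compare_systems,
    correlations,
    icc_2k,
    loa_percent,
    rate_agreement,
    simulate_two_systems,
    temporal_discrepancy,
)


def icc_2k_bruteforce(x):
    """Independent oracle: explicit two-way ANOVA sums of squares by loops."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)


def test_icc_identical_columns_is_one():
    x = np.column_stack([[1.0, 2.0, 3.0, 4.0]] * 2)
    assert icc_2k(x) == pytest.approx(1.0)


def test_icc_constant_matrix_is_one_by_convention():
    assert icc_2k(np.full((5, 2), 3.3)) == 1.0


def test_icc_penalises_constant_offset():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    m = np.column_stack([x, x + 1.0])
    assert icc_2k(m) < 1.0


def test_icc_matches_bruteforce_on_small_integer_matrix():
    m = np.array([[9, 2], [1, 10], [8, 9], [2, 6], [7, 8]], dtype=float)
    assert icc_2k(m) == pytest.approx(icc_2k_bruteforce(m), abs=1e-12)


def test_icc_matches_pingouin_reference():
    """Cross-check against an independent statistics library (ICC2k)."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    m = rng.normal(10, 2, size=(8, 2))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(8), 2),
            "rater": np.tile(["A", "B"], 8),
            "score": m.ravel(),
        }
    )
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    # two-way random, average measures, absolute agreement = pingouin's ICC(A,k)
    icc2k = float(ref.loc[ref["Type"] == "ICC(A,k)", "ICC"].iloc[0])
    assert icc_2k(m) == pytest.approx(icc2k, abs=1e-9)


def test_icc_undefined_below_three_subjects():
    with pytest.warns(UserWarning):
        assert np.isnan(icc_2k(np.array([[1.0, 2.0], [3.0, 4.0]])))


def test_bland_altman_identity_and_bias():
    x = np.array([1.0, 2.0, 3.0])
    assert bland_altman(x, x) == (0.0, 0.0)
    md, loa = bland_altman(x, x + 0.7)
    assert md == pytest.approx(0.7)
    assert loa == pytest.approx(0.0)


def test_bland_altman_hand_computed_halfwidth():
    x = np.zeros(4)
    y = np.array([0.01, -0.01, 0.03, -0.03])
    md, loa = bland_altman(x, y)
    assert md == pytest.approx(0.0)
    assert loa == pytest.approx(1.96 * np.std(y, ddof=1), abs=1e-12)
    assert loa == pytest.approx(0.0506, abs=5e-4)


def test_bland_altman_antisymmetric():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=30), rng.normal(size=30)
    md_xy, loa_xy = bland_altman(x, y)
    md_yx, loa_yx = bland_altman(y, x)
    assert md_xy == pytest.approx(-md_yx)
    assert loa_xy == pytest.approx(loa_yx)


def test_bland_altman_length_mismatch():
    with pytest.raises(ValueError):
        bland_altman(np.zeros(3), np.zeros(4))


def test_loa_percent_grand_mean_convention():
    assert loa_percent(0.049, 0.401, 0.365) == pytest.approx(12.8, abs=0.1)
    assert loa_percent(0.037, 0.387, 0.365) == pytest.approx(9.8, abs=0.1)
    assert loa_percent(0.0, 0.4, 0.4) == 0.0
    assert np.isnan(loa_percent(0.1, 0.5, -0.5))


def test_rating_bands():
    assert rate_agreement(0.95, 1.0) == ("excellent", "excellent")
    assert rate_agreement(0.49, 60.0) == ("poor", "poor")
    # 0.900 is not strictly above the excellent threshold; 4.95 < 5 is
    assert rate_agreement(0.900, 4.95) == ("good", "excellent")
    assert rate_agreement(0.750, 5.0) == ("good", "good")
    assert rate_agreement(0.500, 10.0) == ("moderate", "moderate")
    assert rate_agreement(0.4999, 50.0) == ("poor", "poor")


def test_correlations_linear_and_monotone():
    x = np.linspace(1, 10, 20)
    r, rho = correlations(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert rho == pytest.approx(1.0)
    r, rho = correlations(x, np.exp(x / 3))
    assert rho == pytest.approx(1.0)
    assert r < 1.0


def test_correlations_rank_oracle_with_ties():
    """Spearman equals Pearson on hand-averaged ranks."""
    x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 7.0])
    rank_x = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
    rank_y = np.array([2.0, 1.0, 3.5, 3.5, 5.0])
    expected = np.corrcoef(rank_x, rank_y)[0, 1]
    _, rho = correlations(x, y)
    assert rho == pytest.approx(expected, abs=1e-12)


def test_correlations_zero_variance_absent():
    r, rho = correlations(np.ones(5), np.arange(5.0))
    assert np.isnan(r) and np.isnan(rho)


def test_temporal_discrepancy_worked_example():
    """1.27 cm walkway resolution at 142 cm/s ≈ 9 ms of event-timing blur."""
    assert round(temporal_discrepancy(1.27, 142.0), 3) == 0.009
    with pytest.raises(ValueError):
        temporal_discrepancy(1.27, 0.0)


def test_compare_identical_summaries_is_perfect():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        rng.normal(0.5, 0.05, size=(10, 2)),
        columns=["step_time_mean", "stride_time_mean"],
        index=[f"S{i}" for i in range(10)],
    )
    report = compare_systems(df, df.copy()).table
    assert np.allclose(report["icc"].astype(float), 1.0)
    assert np.allclose(report["loa_percent"].astype(float), 0.0)


def test_compare_constant_bias_recovered():
    cfg = SimulationConfig(n_steps=120, seed=9)
    ref, test = simulate_two_systems(cfg, noise_ref=0.0, noise_test=0.0,
                                     cohort=CohortConfig(n_subjects=12))
    test = test.copy()
    test["step_time_mean"] = test["step_time_mean"] + 0.04
    report = compare_systems(ref, test).table
    assert report.loc["step_time_mean", "mean_diff"] == pytest.approx(0.04, abs=1e-9)


def test_compare_loa_matches_noise_closed_form():
    """Independent per-step noise of fractional SD f propagates to the
    subject-mean difference as √2·f·μ/√n, so the LoA half-width is
    1.96·√2·f·μ/√n."""
    cfg = SimulationConfig(n_steps=238, seed=11)
    f = 0.01
    ref, test = simulate_two_systems(cfg, noise_ref=f, noise_test=f,
                                     cohort=CohortConfig(n_subjects=40))
    report = compare_systems(ref, test).table
    mu = ref["step_time_mean"].mean()
    expected = 1.96 * np.sqrt(2) * f * mu / np.sqrt(cfg.n_steps)
    assert report.loc["step_time_mean", "loa_halfwidth"] == pytest.approx(expected, rel=0.25)


def test_compare_subject_mismatch_uses_intersection():
    rng = np.random.default_rng(3)
    ref = pd.DataFrame({"step_time_mean": rng.normal(0.5, 0.04, 6)},
                       index=[f"S{i}" for i in range(6)])
    test = ref.iloc[1:].copy() + rng.normal(0, 0.001, (5, 1))
    with pytest.warns(UserWarning, match="mismatch"):
        report = compare_systems(ref, test).table
    assert report.loc["step_time_mean", "n"] == 5
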