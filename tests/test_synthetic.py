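"""Synthetic trial generator: reproducibility, moments, degenerate settings."""

import numpy as np
import pandas as pd
import pytest

from clusterni import ComponentParams, TrialScenario, generate_trial, inject_invalid, inject_missingness
from clusterni.exceptions import ConfigurationError
from clusterni.synthetic import scenario_from_file


def _noise_free_scenario(**kw):
    base = dict(
        n_schools_per_arm=4,
        teachers_per_school=3,
        arm_effect=0.0,
        school_sd=0.0,
        residual_sd=0.0,
        missing_rate_baseline=0.0,
        missing_rate_followup=0.0,
        invalid_rate=0.0,
        seed=5,
    )
    base.update(kw)
    return TrialScenario(**base)


def test_same_seed_reproduces_bit_for_bit():
    a = generate_trial(TrialScenario(seed=42))
    b = generate_trial(TrialScenario(seed=42))
    pd.testing.assert_frame_equal(a, b)


def test_different_seeds_differ():
    a = generate_trial(TrialScenario(seed=1))
    b = generate_trial(TrialScenario(seed=2))
    assert not a["total_minutes"].equals(b["total_minutes"])


def test_total_is_sum_of_components(default_records):
    obs = default_records.dropna(subset=["total_minutes"])
    comps = obs[
        ["minutes_pe", "minutes_sport", "minutes_energisers", "minutes_active_lessons"]
    ].sum(axis=1)
    np.testing.assert_allclose(obs["total_minutes"], comps, rtol=1e-9)


def test_arm_structure(default_records):
    per_arm = default_records.groupby("arm")["school_id"].nunique()
    assert per_arm["original"] == 24
    assert per_arm["adapted"] == 24
    # every teacher has one baseline and one follow-up row
    counts = default_records.groupby("teacher_id")["timepoint"].nunique()
    assert (counts == 2).all()


def test_default_scenario_baseline_moments():
    """Arm-level baseline mean/SD sit in the emulated trial's range."""
    rec = generate_trial(TrialScenario(seed=11, missing_rate_baseline=0.0, invalid_rate=0.0))
    base = rec[rec["timepoint"] == "baseline"]
    for arm in ("original", "adapted"):
        vals = base.loc[base["arm"] == arm, "total_minutes"].dropna()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert 122 - 2 * se <= vals.mean() <= 131 + 2 * se
        assert 38 <= vals.std(ddof=1) <= 56


def test_noise_free_followup_is_deterministic_transform():
    sc = _noise_free_scenario()
    rec = generate_trial(sc)
    wide = rec.pivot_table(index="teacher_id", columns="timepoint", values="total_minutes")
    expected = (
        sc.baseline_mean * (1 - sc.baseline_slope)
        + sc.followup_gain
        + sc.baseline_slope * wide["baseline"]
    )
    np.testing.assert_allclose(wide["followup"], expected, rtol=1e-9)
    # arm difference exactly zero in expectation structure: identical transform
    arm = rec.groupby("teacher_id")["arm"].first()
    diffs = (wide["followup"] - expected).groupby(arm).mean()
    np.testing.assert_allclose(diffs, 0.0, atol=1e-9)


def test_degenerate_hurdle_all_zero():
    sc = _noise_free_scenario()
    sc.component_params["energisers"] = ComponentParams(
        zero_prob=[[1.0, 1.0], [1.0, 1.0]], gamma_mean=45.0, gamma_shape=1.2
    )
    rec = generate_trial(sc)
    assert (rec["minutes_energisers"] == 0.0).all()


def test_invalid_scenario_names_field():
    with pytest.raises(ConfigurationError, match="missing_rate_baseline"):
        TrialScenario(missing_rate_baseline=1.5).validate()
    with pytest.raises(ConfigurationError, match="zero_prob"):
        sc = TrialScenario()
        sc.component_params["pe"] = ComponentParams(
            zero_prob=[[2.0, 0.0], [0.0, 0.0]], gamma_mean=1.0, gamma_shape=1.0
        )
        sc.validate()
    with pytest.raises(ConfigurationError, match="proportions"):
        TrialScenario(strata=[(("A", "x"), 0.5)]).validate()


def test_missingness_rate_zero_is_identity(default_records):
    out = inject_missingness(default_records, 0.0, 0.0, seed=3)
    pd.testing.assert_frame_equal(out, default_records)


def test_missingness_rate_one_masks_all_followup(default_records):
    out = inject_missingness(default_records, 0.0, 1.0, seed=3)
    fu = out[out["timepoint"] == "followup"]
    assert fu["total_minutes"].isna().all()
    # identifiers retained
    assert fu["teacher_id"].notna().all() and fu["arm"].notna().all()


def test_missingness_empirical_rate_binomial_bound():
    sc = TrialScenario(
        n_schools_per_arm=50,
        teachers_per_school=10,
        missing_rate_baseline=0.0,
        missing_rate_followup=0.0,
        invalid_rate=0.0,
        seed=8,
    )
    rec = generate_trial(sc)
    out = inject_missingness(rec, 0.3, 0.3, seed=9)
    n = len(out)
    frac = out["total_minutes"].isna().mean()
    half_width = 2.576 * np.sqrt(0.3 * 0.7 / n)
    assert abs(frac - 0.3) < half_width


def test_missingness_rate_validation(default_records):
    with pytest.raises(ConfigurationError):
        inject_missingness(default_records, -0.1, 0.0)
    with pytest.raises(ConfigurationError):
        inject_invalid(default_records, 1.2)


def test_invalid_injection_exceeds_threshold(default_records):
    injected = default_records[default_records["_invalid_injected"]]
    assert (injected["total_minutes"] > 250).all()


def test_invalid_injection_rate_zero():
    sc = TrialScenario(seed=4, invalid_rate=0.0)
    rec = generate_trial(sc)
    assert rec["_invalid_injected"].sum() == 0


def test_invalid_injection_school_count():
    """Rate 0.125 on 48 schools injects into roughly 6 schools."""
    counts = []
    for seed in range(20):
        rec = generate_trial(TrialScenario(seed=seed))
        counts.append(rec.loc[rec["_invalid_injected"], "school_id"].nunique())
    assert 4 <= np.mean(counts) <= 8


def test_between_school_variance_matches_moments():
    """Empirical between-school variance of school means ~ sd_u^2 + sd_e^2/m."""
    sc = TrialScenario(
        n_schools_per_arm=24,
        teachers_per_school=5,
        arm_effect=0.0,
        baseline_slope=0.0,
        school_sd=16.0,
        residual_sd=34.0,
        missing_rate_baseline=0.0,
        missing_rate_followup=0.0,
        invalid_rate=0.0,
    )
    expected = sc.school_sd**2 + sc.residual_sd**2 / 5
    variances = []
    for seed in range(200):
        rec = generate_trial(sc.with_(seed=seed))
        fu = rec[rec["timepoint"] == "followup"]
        means = fu.groupby("school_id")["total_minutes"].mean()
        variances.append(means.var(ddof=1))
    assert abs(np.mean(variances) - expected) / expected < 0.15


def test_hurdle_marginal_mean():
    """Component empirical mean ~= (1 - zero_prob) * gamma_mean."""
    sc = TrialScenario(
        baseline_mean=150.0,
        baseline_sd=30.0,
        followup_gain=0.0,
        missing_rate_baseline=0.0,
        missing_rate_followup=0.0,
        invalid_rate=0.0,
        seed=21,
    )
    sc.component_params["energisers"] = ComponentParams(
        zero_prob=[[0.5, 0.5], [0.5, 0.5]], gamma_mean=40.0, gamma_shape=1.5
    )
    sc.component_params["active_lessons"] = ComponentParams(
        zero_prob=[[1.0, 1.0], [1.0, 1.0]], gamma_mean=25.0, gamma_shape=1.0
    )
    sc.component_params["pe"] = ComponentParams(
        zero_prob=[[1.0, 1.0], [1.0, 1.0]], gamma_mean=55.0, gamma_shape=2.5
    )
    rec = generate_trial(sc)
    vals = rec["minutes_energisers"].dropna()
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 0.5 * 40.0) < 3 * se


def test_scenario_config_file_roundtrip(tmp_path):
    cfg = tmp_path / "scenario.yml"
    cfg.write_text(
        "n_schools_per_arm: 5\n"
        "teachers_per_school: [3, 6]\n"
        "baseline_mean: 110.0\n"
        "arm_effect: -5.0\n"
        "seed: 3\n"
    )
    sc = scenario_from_file(cfg)
    assert sc.n_schools_per_arm == 5
    assert sc.teachers_per_school == (3, 6)
    assert sc.baseline_mean == 110.0
    generate_trial(sc)  # generates without error
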