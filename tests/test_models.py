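"""Outcome models: recovery, conjugate oracle, imputation, hurdle post-processing."""

import numpy as np
import pytest

from clusterni import (
    ComponentParams,
    HurdleSpec,
    LMMSpec,
    MCMCConfig,
    PosteriorSamples,
    TrialScenario,
    build_analysis_dataset,
    exponentiate_interaction,
    fit_gamma_hurdle,
    fit_lmm,
    generate_trial,
    hurdle_minutes_difference,
    validity_filter,
)
from clusterni.exceptions import ConfigurationError, DegenerateLikelihoodError, ModelError
from clusterni.logbook import AnalysisDataset
from clusterni.models import HURDLE_COEF_NAMES

QUICK = MCMCConfig(n_chains=2, n_burnin=300, n_samples=700, seed=17)


def _dataset(scenario: TrialScenario) -> AnalysisDataset:
    valid, excl = validity_filter(generate_trial(scenario))
    return build_analysis_dataset(valid, exclusion_log=excl)


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

def test_lmm_noise_free_recovery():
    """With near-zero noise the group effect is recovered almost exactly."""
    ds = _dataset(
        TrialScenario(
            n_schools_per_arm=6,
            teachers_per_school=4,
            arm_effect=-7.5,
            school_sd=0.01,
            residual_sd=0.01,
            missing_rate_baseline=0.0,
            missing_rate_followup=0.0,
            invalid_rate=0.0,
            seed=41,
        )
    )
    samples = fit_lmm(ds, config=QUICK)
    beta = samples.stacked("beta_group")
    assert abs(beta.mean() - (-7.5)) < 0.5


def test_lmm_no_missing_is_imputation_noop(small_dataset):
    samples = fit_lmm(small_dataset, config=QUICK)
    assert not any(n.endswith("]") and "imp" in n for n in samples.names)
    assert samples.draws.shape == (2, 700, 7 + small_dataset.n_schools)


def test_lmm_imputed_outcomes_stored_as_parameters():
    ds = _dataset(TrialScenario(seed=42))
    samples = fit_lmm(ds, config=QUICK)
    n_miss = ds.baseline_missing().sum() + ds.followup_missing().sum()
    imp_names = [n for n in samples.names if "imp" in n]
    assert len(imp_names) == n_miss
    # imputed follow-ups vary across draws (they are sampled, not point-filled)
    assert samples.stacked(imp_names[0]).std() > 0


def test_lmm_conjugate_toy_matches_closed_form():
    """gamma fixed at 0, SDs fixed: beta_group posterior is Normal in closed form."""
    rng = np.random.default_rng(3)
    m, sig_u, sig_e = 20, 4.0, 10.0
    beta_true, alpha_true = -5.0, 100.0
    S = 4
    arm = np.array([0, 0, 1, 1])
    u = rng.normal(0, sig_u, S)
    sc = np.repeat(np.arange(S), m)
    f = alpha_true + beta_true * arm[sc] + u[sc] + rng.normal(0, sig_e, S * m)
    ds = AnalysisDataset(
        teacher_id=np.array([f"t{i}" for i in range(S * m)]),
        school_index=sc,
        arm_indicator=arm[sc],
        baseline=np.zeros(S * m),
        followup=f,
        school_ids=np.array([f"s{i}" for i in range(S)]),
        school_arm=arm,
    )
    spec = LMMSpec(fixed={"gamma": 0.0, "sigma_school": sig_u, "sigma_resid": sig_e})
    cfg = MCMCConfig(n_chains=4, n_burnin=500, n_samples=2500, seed=19)
    samples = fit_lmm(ds, spec, cfg)
    beta = samples.stacked("beta_group")

    # independent closed form: cluster means ~ N(alpha + beta*g, sig_u^2 + sig_e^2/m)
    ybar = np.array([f[sc == s].mean() for s in range(S)])
    v = sig_u**2 + sig_e**2 / m
    X = np.column_stack([np.ones(S), arm])
    prior_prec = np.eye(2) / 100.0**2
    A = X.T @ X / v + prior_prec
    mean = np.linalg.solve(A, X.T @ ybar / v)
    cov = np.linalg.inv(A)
    from clusterni import effective_sample_size

    ess = effective_sample_size(samples.get("beta_group")[:, :, None])[0]
    mcse = beta.std(ddof=1) / np.sqrt(ess)
    assert abs(beta.mean() - mean[1]) < 3 * mcse
    sd_mcse = beta.std(ddof=1) * np.sqrt(2.0 / ess)
    assert abs(beta.std(ddof=1) - np.sqrt(cov[1, 1])) < 3 * sd_mcse


def test_lmm_all_missing_arm_rejected(small_dataset):
    ds = small_dataset
    broken = AnalysisDataset(
        teacher_id=ds.teacher_id,
        school_index=ds.school_index,
        arm_indicator=ds.arm_indicator,
        baseline=np.where(ds.arm_indicator == 1, np.nan, ds.baseline),
        followup=np.where(ds.arm_indicator == 1, np.nan, ds.followup),
        school_ids=ds.school_ids,
        school_arm=ds.school_arm,
        components=ds.components,
    )
    with pytest.raises(ModelError, match="missing"):
        fit_lmm(broken, config=QUICK)


def test_lmm_informative_requires_hyperparameters(small_dataset):
    with pytest.raises(ConfigurationError, match="beta_prior"):
        fit_lmm(small_dataset, LMMSpec(prior_mode="informative"), QUICK)


def test_lmm_prior_sensitivity_data_dominate(default_dataset):
    """Vague vs weakly-informative priors agree within 1 minute on trial-size data."""
    cfg = MCMCConfig(n_chains=2, n_burnin=300, n_samples=900, seed=23)
    uninf = fit_lmm(default_dataset, LMMSpec(), cfg)
    inf = fit_lmm(
        default_dataset,
        LMMSpec(prior_mode="informative", beta_prior=(0.0, 15.0)),
        cfg,
    )
    delta = abs(uninf.stacked("beta_group").mean() - inf.stacked("beta_group").mean())
    assert delta < 1.0


def test_lmm_missingness_widens_interval():
    """More follow-up missingness -> wider credible interval, on average."""
    widths = []
    for rate in (0.0, 0.3):
        acc = []
        for seed in range(6):
            ds = _dataset(
                TrialScenario(
                    n_schools_per_arm=10,
                    teachers_per_school=5,
                    missing_rate_baseline=0.0,
                    missing_rate_followup=rate,
                    invalid_rate=0.0,
                    seed=100 + seed,
                )
            )
            s = fit_lmm(ds, config=MCMCConfig(2, 200, 500, seed=seed))
            beta = s.stacked("beta_group")
            lo, hi = np.percentile(beta, [2.5, 97.5])
            acc.append(hi - lo)
        widths.append(np.mean(acc))
    assert widths[1] > widths[0]


def test_lmm_seeded_determinism(small_dataset):
    a = fit_lmm(small_dataset, config=MCMCConfig(2, 100, 200, seed=5))
    b = fit_lmm(small_dataset, config=MCMCConfig(2, 100, 200, seed=5))
    np.testing.assert_array_equal(a.draws, b.draws)


# ---------------------------------------------------------------------------
# Gamma-hurdle model
# ---------------------------------------------------------------------------

def test_hurdle_degenerate_components_rejected(small_scenario):
    sc = small_scenario.with_(seed=55)
    sc.component_params = dict(sc.component_params)
    sc.component_params["energisers"] = ComponentParams(
        zero_prob=[[1.0, 1.0], [1.0, 1.0]], gamma_mean=45.0, gamma_shape=1.2
    )
    sc.component_params["pe"] = ComponentParams(
        zero_prob=[[0.0, 0.0], [0.0, 0.0]], gamma_mean=55.0, gamma_shape=2.5
    )
    valid, _ = validity_filter(generate_trial(sc))
    ds = build_analysis_dataset(valid)
    with pytest.raises(DegenerateLikelihoodError, match="all-zero"):
        fit_gamma_hurdle(ds, "energisers", config=QUICK)
    with pytest.raises(DegenerateLikelihoodError, match="no zeros"):
        fit_gamma_hurdle(ds, "pe", config=QUICK)


def test_hurdle_null_interaction_covered(small_dataset):
    """Generator has no time-by-group effect; its ratio CI covers 1."""
    s = fit_gamma_hurdle(small_dataset, "active_lessons", config=QUICK)
    ratio = exponentiate_interaction(s)
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    assert lo <= 1.0 <= hi


def test_hurdle_positive_part_interaction_recovery():
    """A true positive-part ratio of 1.5 lands inside its own 95% CI."""
    sc = TrialScenario(
        n_schools_per_arm=12,
        teachers_per_school=8,
        missing_rate_baseline=0.0,
        missing_rate_followup=0.0,
        invalid_rate=0.0,
        baseline_mean=150.0,
        baseline_sd=25.0,
        arm_effect=0.0,
        followup_gain=0.0,
        seed=77,
    )
    # positive-part mean grid: adapted arm gains x1.5 at follow-up; the other
    # components are switched off so the total never truncates this one
    sc.component_params = dict(sc.component_params)
    sc.component_params["energisers"] = ComponentParams(
        zero_prob=[[0.4, 0.4], [0.4, 0.4]],
        gamma_mean=[[30.0, 30.0], [30.0, 45.0]],
        gamma_shape=2.0,
    )
    for other in ("active_lessons", "pe"):
        sc.component_params[other] = ComponentParams(
            zero_prob=[[1.0, 1.0], [1.0, 1.0]], gamma_mean=30.0, gamma_shape=1.0
        )
    valid, _ = validity_filter(generate_trial(sc))
    ds = build_analysis_dataset(valid)
    s = fit_gamma_hurdle(ds, "energisers", config=MCMCConfig(2, 400, 800, seed=6))
    ratio = exponentiate_interaction(s)
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    assert lo <= 1.5 <= hi
    assert 1.1 < ratio.mean() < 2.0


def _fake_hurdle_samples(a, c, extra=None):
    """PosteriorSamples with constant hurdle coefficients for direct checks."""
    S = 2
    names = list(HURDLE_COEF_NAMES) + [
        "gamma_shape", "sigma_school_zero", "sigma_school_pos",
        "u_zero[0]", "u_zero[1]", "u_pos[0]", "u_pos[1]",
    ]
    vals = np.array(list(a) + list(c) + [2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    draws = np.tile(vals, (2, 600, 1))
    if extra is not None:
        draws = draws + extra
    return PosteriorSamples(names, draws)


def test_exponentiate_interaction_direct():
    vals = np.array([-0.1, 0.0, 0.1])
    s = _fake_hurdle_samples([0, 0, 0, 0], [0, 0, 0, 0])
    s.draws[:, :, 7] = 0.0
    s.draws[0, :3, 7] = vals
    out = exponentiate_interaction(s)
    assert out[0] == pytest.approx(np.exp(-0.1))
    expected_mean = (np.exp(-0.1) + 1.0 + np.exp(0.1)) / 3.0
    assert np.mean(out[:3]) == pytest.approx(expected_mean)


def test_hurdle_minutes_difference_zero_when_arms_equal():
    # no group or interaction terms in either part -> difference identically 0
    s = _fake_hurdle_samples([0.2, 0.5, 0.0, 0.0], [3.0, 0.3, 0.0, 0.0])
    out = hurdle_minutes_difference(s)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_hurdle_minutes_difference_collapses_without_zeros():
    # pi ~ 0 everywhere: reduces to difference-in-differences of gamma means
    a = [-40.0, 0.0, 0.0, 0.0]
    c = [np.log(30.0), np.log(1.2), np.log(1.1), np.log(1.5)]
    s = _fake_hurdle_samples(a, c)
    out = hurdle_minutes_difference(s)
    mu = lambda t, g: 30.0 * 1.2**t * 1.1**g * 1.5 ** (t * g)
    expected = (mu(1, 1) - mu(0, 1)) - (mu(1, 0) - mu(0, 0))
    np.testing.assert_allclose(out, expected, rtol=1e-9)


def test_hurdle_minutes_difference_hand_evaluated():
    a = [0.4, -0.8, 0.1, -0.3]
    c = [3.2, 0.25, -0.05, 0.1]
    s = _fake_hurdle_samples(a, c)
    out = hurdle_minutes_difference(s)

    def cell(t, g):
        eta = a[0] + a[1] * t + a[2] * g + a[3] * t * g
        pi = 1.0 / (1.0 + np.exp(-eta))
        mu = np.exp(c[0] + c[1] * t + c[2] * g + c[3] * t * g)
        return (1 - pi) * mu

    expected = (cell(1, 1) - cell(0, 1)) - (cell(1, 0) - cell(0, 0))
    np.testing.assert_allclose(out, expected, rtol=1e-9)


def test_hurdle_seeded_determinism(small_dataset):
    cfg = MCMCConfig(2, 50, 100, seed=8)
    a = fit_gamma_hurdle(small_dataset, "energisers", config=cfg)
    b = fit_gamma_hurdle(small_dataset, "energisers", config=cfg)
    np.testing.assert_array_equal(a.draws, b.draws)
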