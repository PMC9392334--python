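"""Posterior draws -> headline trial quantities.

For each outcome the analysis reports the posterior mean between-group
difference with an equal-tailed 95% credible interval, the binary interval
decision against the pre-specified margin, the posterior probability of
noninferiority (the exact fraction of draws on the non-inferior side of
Delta), and a clustering summary: the proportion of posterior-predictive
outcome variance attributable to between-school effects, a Bayesian analogue
of the intraclass correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SummaryError
from .logbook import AnalysisDataset
from .margins import MarginSpec, noninferior_by_interval
from .mcmc import PosteriorSamples
from .models import HURDLE_COEF_NAMES

__all__ = [
    "summarize_difference",
    "prob_noninferiority",
    "variance_ratio",
    "VarianceRatioResult",
    "NoninferiorityResult",
    "build_results_table",
]


def summarize_difference(draws: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Posterior mean and equal-tailed 95% credible interval.

    Requires at least 1000 draws so the 2.5/97.5 percentiles are estimable.
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size < 1000:
        raise SummaryError(f"need >= 1000 draws to summarise, got {draws.size}")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), (float(lo), float(hi))


def prob_noninferiority(draws: np.ndarray, margin: MarginSpec) -> float:
    """Exact fraction of difference draws on the non-inferior side of Delta.

    With a higher-is-better outcome, a draw is non-inferior when it is at or
    above the (negative) margin; the complement is the fraction of draws
    crossing Delta.
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    return float(np.mean(draws >= margin.delta))


# ---------------------------------------------------------------------------
# Variance ratio (Bayesian ICC analogue)
# ---------------------------------------------------------------------------

@dataclass
class VarianceRatioResult:
    """Clustering proportion draws plus the literal marginal/conditional quotient.

    ``draws`` holds per-posterior-draw values of
    (marginal variance - conditional variance) / marginal variance, where both
    variances come from simulated posterior-predictive replicates sharing
    common random numbers (so a model with no clustering gives exactly zero,
    and weak clustering can produce negative values, as reported intervals
    sometimes do).  ``quotient_draws`` carries marginal/conditional for
    verbose output.
    """

    draws: np.ndarray
    quotient_draws: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws, [2.5, 97.5])
        return float(lo), float(hi)


def variance_ratio(
    samples: PosteriorSamples,
    dataset: AnalysisDataset,
    model: str = "lmm",
    component: str | None = None,
    seed: int = 0,
) -> VarianceRatioResult:
    """Proportion of posterior-predictive variance attributable to clustering.

    Per posterior draw, one predictive replicate of the outcome vector is
    simulated twice over the analysis design: marginally (school effects
    re-drawn from their population distribution) and conditionally (school
    effects held at their posterior-drawn values, so they contribute no
    predictive spread).  Residual-level random numbers are shared between the
    two replicates; the per-draw summary is (Vm - Vc) / Vm.
    """
    rng = np.random.default_rng(seed)
    if model == "lmm":
        return _variance_ratio_lmm(samples, dataset, rng)
    if model == "hurdle":
        if component is None:
            raise ValueError("component required for hurdle variance ratio")
        return _variance_ratio_hurdle(samples, dataset, component, rng)
    raise ValueError(f"unknown model kind {model!r}")


def _variance_ratio_lmm(
    samples: PosteriorSamples, dataset: AnalysisDataset, rng: np.random.Generator
) -> VarianceRatioResult:
    sig_u = samples.stacked("sigma_school")
    sig_e = samples.stacked("sigma_resid")
    d = sig_u.size
    n = dataset.n_teachers
    S = dataset.n_schools
    sc = dataset.school_index
    eps = rng.standard_normal((d, n)) * sig_e[:, None]
    u_rep = rng.standard_normal((d, S)) * sig_u[:, None]
    marg_dev = u_rep[:, sc] + eps  # school effects part of the predictive noise
    cond_dev = eps  # school effects conditioned on: only residual spread left
    vm = marg_dev.var(axis=1, ddof=1)
    vc = cond_dev.var(axis=1, ddof=1)
    return VarianceRatioResult(draws=(vm - vc) / vm, quotient_draws=vm / vc)


def _variance_ratio_hurdle(
    samples: PosteriorSamples,
    dataset: AnalysisDataset,
    component: str,
    rng: np.random.Generator,
) -> VarianceRatioResult:
    data = dataset.components[component]
    t = data["time"].to_numpy(dtype=float)
    g = data["arm"].to_numpy(dtype=float)
    sc = data["school_index"].to_numpy()
    n = t.size
    S = dataset.n_schools
    X = np.column_stack([np.ones_like(t), t, g, t * g])

    a = np.column_stack([samples.stacked(nm) for nm in HURDLE_COEF_NAMES[:4]])
    c = np.column_stack([samples.stacked(nm) for nm in HURDLE_COEF_NAMES[4:]])
    k = samples.stacked("gamma_shape")
    tau_v = samples.stacked("sigma_school_zero")
    tau_w = samples.stacked("sigma_school_pos")
    v = np.column_stack([samples.stacked(f"u_zero[{s}]") for s in range(S)])
    w = np.column_stack([samples.stacked(f"u_pos[{s}]") for s in range(S)])
    d = k.size

    # common random numbers shared by the marginal and conditional replicates
    u_zero = rng.uniform(size=(d, n))
    gam = rng.standard_gamma(np.broadcast_to(k[:, None], (d, n)))
    v_rep = rng.standard_normal((d, S)) * tau_v[:, None]
    w_rep = rng.standard_normal((d, S)) * tau_w[:, None]

    eta_fix = a @ X.T  # (d, n)
    logmu_fix = c @ X.T

    def replicate(v_eff: np.ndarray, w_eff: np.ndarray) -> np.ndarray:
        eta = eta_fix + v_eff[:, sc]
        pi = 1.0 / (1.0 + np.exp(-eta))
        mu = np.exp(logmu_fix + w_eff[:, sc])
        y = np.where(u_zero < pi, 0.0, gam * mu / k[:, None])
        return y

    vm = replicate(v_rep, w_rep).var(axis=1, ddof=1)
    vc = replicate(v, w).var(axis=1, ddof=1)
    return VarianceRatioResult(draws=(vm - vc) / vm, quotient_draws=vm / vc)


# ---------------------------------------------------------------------------
# Per-outcome result container and results table
# ---------------------------------------------------------------------------

@dataclass
class NoninferiorityResult:
    """Headline quantities for one outcome."""

    outcome: str
    estimate: float
    ci: tuple[float, float]
    margin: MarginSpec
    prob_noninferior: float
    interval_decision: bool
    estimate_scale: str = "minutes"  # "minutes" for the LMM, "ratio" for hurdle rows
    variance_ratio_mean: float = np.nan
    variance_ratio_ci: tuple[float, float] = (np.nan, np.nan)
    descriptives: dict | None = None


_TABLE_COLUMNS = [
    "outcome",
    "baseline_mean_original",
    "baseline_sd_original",
    "followup_mean_original",
    "followup_sd_original",
    "baseline_mean_adapted",
    "baseline_sd_adapted",
    "followup_mean_adapted",
    "followup_sd_adapted",
    "estimate",
    "ci_lower",
    "ci_upper",
    "estimate_scale",
    "margin",
    "prob_noninferior",
    "interval_noninferior",
    "variance_ratio",
    "variance_ratio_lower",
    "variance_ratio_upper",
]


def build_results_table(results: list[NoninferiorityResult]) -> pd.DataFrame:
    """One row per outcome, mirroring a trial-report results table.

    Hurdle rows carry ``estimate_scale == 'ratio'`` (exponentiated
    time-by-group coefficient); the primary row is on the minutes scale.
    An empty input yields a header-only table.
    """
    rows = []
    for r in results:
        desc = r.descriptives or {}
        rows.append(
            {
                "outcome": r.outcome,
                "baseline_mean_original": desc.get(("original", "baseline", "mean"), np.nan),
                "baseline_sd_original": desc.get(("original", "baseline", "sd"), np.nan),
                "followup_mean_original": desc.get(("original", "followup", "mean"), np.nan),
                "followup_sd_original": desc.get(("original", "followup", "sd"), np.nan),
                "baseline_mean_adapted": desc.get(("adapted", "baseline", "mean"), np.nan),
                "baseline_sd_adapted": desc.get(("adapted", "baseline", "sd"), np.nan),
                "followup_mean_adapted": desc.get(("adapted", "followup", "mean"), np.nan),
                "followup_sd_adapted": desc.get(("adapted", "followup", "sd"), np.nan),
                "estimate": r.estimate,
                "ci_lower": r.ci[0],
                "ci_upper": r.ci[1],
                "estimate_scale": r.estimate_scale,
                "margin": r.margin.delta,
                "prob_noninferior": r.prob_noninferior,
                "interval_noninferior": r.interval_decision,
                "variance_ratio": r.variance_ratio_mean,
                "variance_ratio_lower": r.variance_ratio_ci[0],
                "variance_ratio_upper": r.variance_ratio_ci[1],
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def make_result(
    outcome: str,
    diff_draws: np.ndarray,
    margin: MarginSpec,
    estimate_draws: np.ndarray | None = None,
    estimate_scale: str = "minutes",
    vr: VarianceRatioResult | None = None,
    descriptives: dict | None = None,
) -> NoninferiorityResult:
    """Assemble a :class:`NoninferiorityResult` from draw vectors.

    ``diff_draws`` (minutes scale) drive the probability of noninferiority and
    the interval decision; ``estimate_draws`` (defaulting to ``diff_draws``)
    drive the reported estimate and credible interval — for hurdle outcomes
    these are the exponentiated-interaction ratio draws.
    """
    est_draws = diff_draws if estimate_draws is None else estimate_draws
    estimate, ci = summarize_difference(est_draws)
    _, diff_ci = summarize_difference(diff_draws)
    return NoninferiorityResult(
        outcome=outcome,
        estimate=estimate,
        ci=ci,
        margin=margin,
        prob_noninferior=prob_noninferiority(diff_draws, margin),
        interval_decision=noninferior_by_interval(diff_ci[0], margin.delta),
        estimate_scale=estimate_scale,
        variance_ratio_mean=vr.mean if vr is not None else np.nan,
        variance_ratio_ci=vr.ci if vr is not None else (np.nan, np.nan),
        descriptives=descriptives,
    )
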