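"""End-to-end orchestration: ingest -> filter -> models -> summaries -> costs.

A single master seed deterministically derives independent per-stage seeds
(generation, each model's chains, variance-ratio simulation, bootstrap), so a
rerun with the same configuration reproduces every output byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .costs import (
    bootstrap_uncertainty,
    packaged_ledger_path,
    per_school_costs,
    read_ledger,
    summarise_costs,
)
from .exceptions import ConfigurationError, PipelineError
from .logbook import (
    AnalysisDataset,
    build_analysis_dataset,
    descriptive_stats,
    read_logbooks,
    validity_filter,
    write_logbooks,
)
from .margins import DEFAULT_MARGINS, MarginSpec, compute_margin
from .mcmc import MCMCConfig
from .models import (
    HurdleSpec,
    LMMSpec,
    exponentiate_interaction,
    fit_gamma_hurdle,
    fit_lmm,
    hurdle_minutes_difference,
)
from .summary import build_results_table, make_result, variance_ratio
from .synthetic import TrialScenario, generate_trial

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_flow_summary"]

logger = logging.getLogger("clusterni")

HURDLE_OUTCOMES = ("energisers", "active_lessons", "pe")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    scenario: TrialScenario | None = None
    logbook_path: str | None = None
    ledger_path: str | None = None
    outcomes: list = field(
        default_factory=lambda: ["total", "energisers", "active_lessons", "pe"]
    )
    margins: dict = field(default_factory=lambda: dict(DEFAULT_MARGINS))
    prior_mode: str = "uninformative"
    beta_prior: tuple | None = None
    n_chains: int = 4
    n_burnin: int = 10_000
    n_samples: int = 10_000
    bootstrap_reps: int = 1000
    include_cost: bool = True
    out_dir: str | None = None
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if self.scenario is None and self.logbook_path is None:
            raise ConfigurationError("either a synthetic scenario or a logbook path is required")
        for p_name in ("logbook_path", "ledger_path"):
            p = getattr(self, p_name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{p_name} does not exist: {p}")
        unknown = [o for o in self.outcomes if o != "total" and o not in HURDLE_OUTCOMES]
        if unknown:
            raise ConfigurationError(f"unknown outcomes: {unknown}")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("run config must be a key: value mapping")
        kwargs: dict = {}
        if "scenario" in raw:
            kwargs["scenario"] = TrialScenario.from_dict(raw["scenario"])
        for key in ("logbook_path", "ledger_path", "outcomes", "bootstrap_reps", "include_cost",
                    "out_dir", "seed", "verbose"):
            if key in raw:
                kwargs[key] = raw[key]
        if "mcmc" in raw:
            m = raw["mcmc"]
            for key in ("n_chains", "n_burnin", "n_samples"):
                if key in m:
                    kwargs[key] = int(m[key])
        if "prior" in raw:
            p = raw["prior"]
            kwargs["prior_mode"] = p.get("mode", "uninformative")
            if "beta_mean" in p:
                kwargs["beta_prior"] = (float(p["beta_mean"]), float(p["beta_sd"]))
        if "margins" in raw:
            margins = dict(DEFAULT_MARGINS)
            for outcome, m in raw["margins"].items():
                if "delta" in m:
                    delta = float(m["delta"])
                    margins[outcome] = MarginSpec(0.5, 2.0 * abs(delta), delta)
                else:
                    margins[outcome] = compute_margin(
                        float(m["retained_proportion"]), float(m["reference_lower_bound"])
                    )
            kwargs["margins"] = margins
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class RunReport:
    """Outputs of one pipeline run."""

    results: list
    results_table: pd.DataFrame
    diagnostics: pd.DataFrame
    flow_summary: pd.DataFrame
    cost_summary: pd.DataFrame | None
    cost_intervals: dict | None
    log_lines: list
    dataset: AnalysisDataset
    records: pd.DataFrame
    complete: bool = True


def _stage_seeds(master: int) -> dict[str, int]:
    names = [
        "generation",
        "lmm",
        "hurdle_energisers",
        "hurdle_active_lessons",
        "hurdle_pe",
        "vr_lmm",
        "vr_energisers",
        "vr_active_lessons",
        "vr_pe",
        "bootstrap",
    ]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and (optionally) write the report bundle.

    Stages run in order: ingest, validity filter, dataset assembly, primary
    linear mixed model, hurdle models, noninferiority summaries, flow
    summary, costing.  Any stage failure raises :class:`PipelineError` with a
    stage-labelled message.
    """
    config.validate()
    logging.basicConfig(level=logging.DEBUG if config.verbose else logging.INFO)
    seeds = _stage_seeds(config.seed)
    log: list[str] = [
        f"clusterni {__version__}",
        f"master seed: {config.seed}",
        f"prior mode: {config.prior_mode}",
        f"mcmc: {config.n_chains} chains x ({config.n_burnin} burn-in + {config.n_samples} draws)",
    ]
    for outcome in config.outcomes:
        m = config.margins[outcome]
        log.append(
            f"margin[{outcome}]: delta={m.delta} "
            f"(retained {m.retained_proportion}, reference bound {m.reference_lower_bound})"
        )

    # -- ingest ----------------------------------------------------------
    try:
        if config.logbook_path is not None:
            records = read_logbooks(config.logbook_path)
            log.append(f"ingest: read {len(records)} records from {config.logbook_path}")
        else:
            scenario = config.scenario.with_(seed=seeds["generation"])
            records = generate_trial(scenario)
            log.append(f"ingest: generated {len(records)} synthetic records")
    except Exception as exc:
        raise PipelineError(f"[ingest] {exc}") from exc

    # -- validity filter + dataset ---------------------------------------
    try:
        valid, excluded = validity_filter(records)
        dataset = build_analysis_dataset(valid, exclusion_log=excluded)
        log.append(
            f"validity filter: {len(valid)} valid records, {len(excluded)} excluded (invalid_total)"
        )
        log.append(
            f"analysis dataset: {dataset.n_teachers} teachers in {dataset.n_schools} schools"
        )
    except Exception as exc:
        raise PipelineError(f"[filter] {exc}") from exc

    desc = descriptive_stats(valid)

    def desc_map(outcome: str) -> dict:
        sub = desc[desc["outcome"] == outcome]
        return {
            (r["arm"], r["timepoint"], k): r[k]
            for _, r in sub.iterrows()
            for k in ("mean", "sd")
        }

    mcfg = dict(n_chains=config.n_chains, n_burnin=config.n_burnin, n_samples=config.n_samples)
    results = []
    diag_frames = []

    # -- primary outcome --------------------------------------------------
    if "total" in config.outcomes:
        try:
            lmm_spec = LMMSpec(prior_mode=config.prior_mode, beta_prior=config.beta_prior)
            samples = fit_lmm(dataset, lmm_spec, MCMCConfig(seed=seeds["lmm"], **mcfg))
            vr = variance_ratio(samples, dataset, model="lmm", seed=seeds["vr_lmm"])
            results.append(
                make_result(
                    "total",
                    samples.stacked("beta_group"),
                    config.margins["total"],
                    vr=vr,
                    descriptives=desc_map("total"),
                )
            )
            diag = samples.diagnostics().head(7).assign(outcome="total")
            diag_frames.append(diag)
            log.extend(samples.convergence_warnings())
        except Exception as exc:
            raise PipelineError(f"[lmm] {exc}") from exc

    # -- component outcomes ----------------------------------------------
    for comp in [o for o in config.outcomes if o in HURDLE_OUTCOMES]:
        try:
            h_spec = HurdleSpec(prior_mode="uninformative")
            samples = fit_gamma_hurdle(
                dataset, comp, h_spec, MCMCConfig(seed=seeds[f"hurdle_{comp}"], **mcfg)
            )
            ratio = exponentiate_interaction(samples)
            minutes = hurdle_minutes_difference(samples, dataset)
            vr = variance_ratio(
                samples, dataset, model="hurdle", component=comp, seed=seeds[f"vr_{comp}"]
            )
            results.append(
                make_result(
                    comp,
                    minutes,
                    config.margins[comp],
                    estimate_draws=ratio,
                    estimate_scale="ratio",
                    vr=vr,
                    descriptives=desc_map(comp),
                )
            )
            diag_frames.append(samples.diagnostics().head(11).assign(outcome=comp))
            log.extend(samples.convergence_warnings())
        except Exception as exc:
            raise PipelineError(f"[hurdle:{comp}] {exc}") from exc

    results_table = build_results_table(results)
    diagnostics = (
        pd.concat(diag_frames, ignore_index=True)
        if diag_frames
        else pd.DataFrame(columns=["parameter", "rhat", "ess", "outcome"])
    )
    flow = make_flow_summary(dataset.exclusion_log, dataset)

    # -- costing ----------------------------------------------------------
    cost_summary_df = None
    cost_intervals = None
    if config.include_cost:
        try:
            ledger_path = config.ledger_path or packaged_ledger_path()
            items = read_ledger(ledger_path)
            summary = summarise_costs(items)
            cost_intervals = bootstrap_uncertainty(
                per_school_costs(items), n_reps=config.bootstrap_reps, seed=seeds["bootstrap"]
            )
            rows = []
            for arm in ("original", "adapted"):
                rows.append(
                    {
                        "arm": arm,
                        "total": summary.total[arm],
                        "total_lower": cost_intervals[f"total_{arm}"][0],
                        "total_upper": cost_intervals[f"total_{arm}"][1],
                        "per_school": summary.per_school[arm],
                        "per_school_rounded": summary.per_school_rounded[arm],
                        "per_school_lower": cost_intervals[f"per_school_{arm}"][0],
                        "per_school_upper": cost_intervals[f"per_school_{arm}"][1],
                        "n_schools": summary.n_schools[arm],
                    }
                )
            rows.append(
                {
                    "arm": "difference",
                    "total": summary.difference_total,
                    "total_lower": cost_intervals["difference_total"][0],
                    "total_upper": cost_intervals["difference_total"][1],
                    "per_school": summary.difference_per_school,
                    "per_school_rounded": round(summary.difference_per_school),
                    "per_school_lower": cost_intervals["difference_per_school"][0],
                    "per_school_upper": cost_intervals["difference_per_school"][1],
                    "n_schools": sum(summary.n_schools.values()),
                }
            )
            cost_summary_df = pd.DataFrame(rows)
            log.append(
                f"costing: bootstrap {config.bootstrap_reps} reps, "
                f"saving {summary.difference_total:.0f} total / "
                f"{summary.difference_per_school:.0f} per school"
            )
        except Exception as exc:
            raise PipelineError(f"[cost] {exc}") from exc

    report = RunReport(
        results=results,
        results_table=results_table,
        diagnostics=diagnostics,
        flow_summary=flow,
        cost_summary=cost_summary_df,
        cost_intervals=cost_intervals,
        log_lines=log,
        dataset=dataset,
        records=records,
    )
    if config.out_dir is not None:
        _write_bundle(report, config)
    return report


def _write_bundle(report: RunReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.results_table.to_csv(out / "results_table.csv", index=False)
    report.diagnostics.to_csv(out / "diagnostics.csv", index=False)
    report.flow_summary.to_csv(out / "flow_summary.csv", index=False)
    if report.cost_summary is not None:
        report.cost_summary.to_csv(out / "cost_summary.csv", index=False)
    write_logbooks(report.records, out / "records.csv")
    (out / "run_log.txt").write_text("\n".join(report.log_lines) + "\n")


def make_flow_summary(exclusion_log: pd.DataFrame, dataset: AnalysisDataset) -> pd.DataFrame:
    """Participant-flow counts per arm, mirroring a trial flow chart.

    ``schools_valid_data`` counts schools with no invalid record (the
    flow-chart tally of schools contributing fully valid data);
    ``schools_contributing`` counts schools with at least one analysable
    teacher (teacher-level exclusion keeps partially valid schools in the
    analysis).
    """
    arms = ("original", "adapted")
    excl = exclusion_log if len(exclusion_log) else pd.DataFrame(
        columns=["school_id", "teacher_id", "arm"]
    )
    rows = []
    for code, arm in enumerate(arms):
        in_arm = dataset.arm_indicator == code
        schools_analysed = set(dataset.school_ids[dataset.school_arm == code])
        teachers_analysed = set(dataset.teacher_id[in_arm])
        excl_arm = excl[excl["arm"] == arm] if len(excl) else excl
        schools_invalid = set(excl_arm["school_id"]) if len(excl_arm) else set()
        teachers_invalid = set(excl_arm["teacher_id"]) if len(excl_arm) else set()
        schools_enrolled = schools_analysed | schools_invalid
        teachers_enrolled = teachers_analysed | teachers_invalid
        rows.append(
            {
                "arm": arm,
                "schools_enrolled": len(schools_enrolled),
                "teachers_enrolled": len(teachers_enrolled),
                "records_excluded_invalid": int(len(excl_arm)),
                "schools_with_invalid": len(schools_invalid),
                "schools_valid_data": len(schools_enrolled) - len(schools_invalid),
                "schools_contributing": len(schools_analysed),
                "teachers_analysed": int(in_arm.sum()),
                "baseline_observed": int((~np.isnan(dataset.baseline[in_arm])).sum()),
                "followup_observed": int((~np.isnan(dataset.followup[in_arm])).sum()),
            }
        )
    total_row = {"arm": "all"}
    for key in rows[0]:
        if key != "arm":
            total_row[key] = sum(r[key] for r in rows)
    rows.append(total_row)
    return pd.DataFrame(rows)
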