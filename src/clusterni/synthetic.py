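"""Synthetic cluster-randomised trial generator.

Emulates the structure of a two-arm school-based implementation trial: schools
randomised 1:1 (stratified by region and geolocation), teachers nested in
schools, and weekly scheduled physical-activity minutes recorded in a logbook
at baseline and 12-month follow-up.  Total weekly minutes follow a Normal
cluster model (school random intercept at follow-up, baseline carried as a
covariate); the component minutes (energisers, active lessons, PE) follow
hurdle distributions — a point mass at zero plus a right-skewed gamma positive
part — with a sport/other remainder absorbing the difference so the recorded
total is exactly the sum of its components.

Default parameters are calibrated to the marginal moments of the emulated
trial: baseline total ≈ 126 (SD 46) minutes/week, a follow-up gain of ≈ 36
minutes, a true arm effect of −7.5 minutes, and a between-school SD giving a
baseline-style intraclass proportion of roughly 0.17.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError

__all__ = [
    "ComponentParams",
    "TrialScenario",
    "generate_trial",
    "inject_missingness",
    "inject_invalid",
    "scenario_from_file",
    "COMPONENTS",
    "LOGBOOK_COLUMNS",
]

#: hurdle-modelled activity components (sport is a remainder, not hurdle-modelled)
COMPONENTS = ("energisers", "active_lessons", "pe")

#: canonical logbook CSV column order
LOGBOOK_COLUMNS = [
    "school_id",
    "teacher_id",
    "arm",
    "region",
    "geolocation",
    "timepoint",
    "minutes_pe",
    "minutes_sport",
    "minutes_energisers",
    "minutes_active_lessons",
]

ARMS = ("original", "adapted")
TIMEPOINTS = ("baseline", "followup")


@dataclass
class ComponentParams:
    """Hurdle parameters for one activity component.

    ``zero_prob`` is a 2x2 grid indexed [timepoint, arm] (baseline/followup x
    original/adapted).  ``gamma_mean`` may be a scalar (shared across design
    points) or a matching 2x2 grid; ``gamma_shape`` is shared.
    """

    zero_prob: Sequence[Sequence[float]]
    gamma_mean: float | Sequence[Sequence[float]]
    gamma_shape: float

    def zero_prob_array(self) -> np.ndarray:
        return np.asarray(self.zero_prob, dtype=float).reshape(2, 2)

    def gamma_mean_array(self) -> np.ndarray:
        g = np.asarray(self.gamma_mean, dtype=float)
        if g.ndim == 0:
            return np.full((2, 2), float(g))
        return g.reshape(2, 2)


def _default_components() -> dict[str, ComponentParams]:
    return {
        "energisers": ComponentParams(
            zero_prob=[[0.60, 0.60], [0.13, 0.13]], gamma_mean=45.0, gamma_shape=1.2
        ),
        "active_lessons": ComponentParams(
            zero_prob=[[0.60, 0.60], [0.40, 0.40]], gamma_mean=25.0, gamma_shape=1.0
        ),
        "pe": ComponentParams(
            zero_prob=[[0.13, 0.13], [0.04, 0.04]], gamma_mean=55.0, gamma_shape=2.5
        ),
    }


def _default_strata() -> list[tuple[tuple[str, str], float]]:
    # region x geolocation allocation mirroring the emulated catchment:
    # two health regions (8 vs 40 of 48 schools), roughly 46% major-city.
    return [
        (("HNE", "major_city"), 18 / 48),
        (("HNE", "regional"), 22 / 48),
        (("CC", "major_city"), 4 / 48),
        (("CC", "regional"), 4 / 48),
    ]


@dataclass
class TrialScenario:
    """Data-generating configuration for one synthetic trial realisation."""

    n_schools_per_arm: int = 24
    teachers_per_school: int | tuple[int, int] = (4, 7)
    strata: list = field(default_factory=_default_strata)
    baseline_mean: float = 126.0
    baseline_sd: float = 46.0
    arm_effect: float = -7.5
    baseline_slope: float = 0.25
    followup_gain: float = 36.0
    school_sd: float = 16.0
    residual_sd: float = 34.0
    component_params: dict = field(default_factory=_default_components)
    missing_rate_baseline: float = 0.05
    missing_rate_followup: float = 0.30
    invalid_rate: float = 0.125
    seed: int = 0

    def validate(self) -> None:
        if self.n_schools_per_arm < 1:
            raise ConfigurationError(f"n_schools_per_arm must be >= 1, got {self.n_schools_per_arm}")
        lo, hi = self._teacher_range()
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"teachers_per_school invalid: {self.teachers_per_school}")
        for name in ("baseline_sd", "school_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        props = [p for _, p in self.strata]
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("strata allocation proportions must be >= 0 and sum to 1")
        for rate_name in ("missing_rate_baseline", "missing_rate_followup", "invalid_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{rate_name} must be in [0, 1], got {r}")
        for comp, params in self.component_params.items():
            zp = params.zero_prob_array()
            if np.any(zp < 0) or np.any(zp > 1):
                raise ConfigurationError(f"component_params[{comp}].zero_prob must be in [0, 1]")
            if np.any(params.gamma_mean_array() <= 0):
                raise ConfigurationError(f"component_params[{comp}].gamma_mean must be > 0")
            if params.gamma_shape <= 0:
                raise ConfigurationError(f"component_params[{comp}].gamma_shape must be > 0")

    def _teacher_range(self) -> tuple[int, int]:
        if isinstance(self.teachers_per_school, (tuple, list)):
            lo, hi = self.teachers_per_school
            return int(lo), int(hi)
        return int(self.teachers_per_school), int(self.teachers_per_school)

    def with_(self, **kwargs) -> "TrialScenario":
        """Copy of the scenario with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialScenario":
        d = dict(d)
        if "component_params" in d:
            d["component_params"] = {
                name: ComponentParams(**cp) if isinstance(cp, dict) else cp
                for name, cp in d["component_params"].items()
            }
        if "strata" in d:
            d["strata"] = [((str(s[0][0]), str(s[0][1])), float(s[1])) for s in d["strata"]]
        if "teachers_per_school" in d and isinstance(d["teachers_per_school"], list):
            d["teachers_per_school"] = tuple(d["teachers_per_school"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**d)


def scenario_from_file(path) -> TrialScenario:
    """Load a scenario from a plain-text key/value (YAML mapping) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("scenario file must contain a key: value mapping")
    return TrialScenario.from_dict(data)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _allocate_strata(scenario: TrialScenario) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Stratum label per school and a balanced 0/1 arm assignment.

    Stratum counts use largest-remainder apportionment of the configured
    proportions; arms alternate within each stratum (stratified 1:1
    randomisation), with a final fix-up so each arm has exactly
    n_schools_per_arm schools.
    """
    total = 2 * scenario.n_schools_per_arm
    props = np.array([p for _, p in scenario.strata], dtype=float)
    raw = props * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(counts)]] += 1
    labels: list[tuple[str, str]] = []
    arms: list[int] = []
    n_arm = [0, 0]
    for (label, _), c in zip(scenario.strata, counts):
        for j in range(c):
            start = 0 if n_arm[0] <= n_arm[1] else 1
            a = (start + j) % 2
            labels.append(label)
            arms.append(a)
            n_arm[a] += 1
    arms_arr = np.array(arms)
    # fix-up: flip surplus schools until the arms balance exactly
    while n_arm[0] != n_arm[1]:
        over = 0 if n_arm[0] > n_arm[1] else 1
        idx = int(np.nonzero(arms_arr == over)[0][-1])
        arms_arr[idx] = 1 - over
        n_arm[over] -= 1
        n_arm[1 - over] += 1
    return labels, arms_arr


def generate_trial(scenario: TrialScenario) -> pd.DataFrame:
    """Generate one trial realisation as long-format teacher-week records.

    Returns a DataFrame with the logbook columns plus ``total_minutes`` and an
    internal ``_invalid_injected`` flag; ``attrs['truth']`` records the
    generating quantities (scenario, school intercepts, counts) for test
    bookkeeping.  Missingness and invalid-record injection are applied at the
    scenario's configured rates.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    core_seed, miss_seed, invalid_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    rng = np.random.default_rng(core_seed)

    n_schools = 2 * scenario.n_schools_per_arm
    labels, school_arm = _allocate_strata(scenario)
    lo, hi = scenario._teacher_range()
    teachers_per_school = (
        np.full(n_schools, lo) if lo == hi else rng.integers(lo, hi + 1, size=n_schools)
    )
    school_ids = [f"s{k:03d}" for k in range(n_schools)]
    u_school = rng.normal(0.0, scenario.school_sd, size=n_schools)

    # teacher-level arrays
    sc = np.repeat(np.arange(n_schools), teachers_per_school)
    n_teachers = sc.size
    arm = school_arm[sc]
    teacher_ids = np.array(
        [f"{school_ids[s]}_t{j:02d}" for s, j in zip(sc, _within_school_counter(sc))]
    )

    b_target = rng.normal(scenario.baseline_mean, scenario.baseline_sd, size=n_teachers)
    f_target = (
        scenario.baseline_mean * (1.0 - scenario.baseline_slope)
        + scenario.followup_gain
        + scenario.baseline_slope * b_target
        + scenario.arm_effect * arm
        + u_school[sc]
        + rng.normal(0.0, scenario.residual_sd, size=n_teachers)
    )
    targets = {"baseline": np.maximum(b_target, 0.0), "followup": np.maximum(f_target, 0.0)}

    frames = []
    for t_idx, timepoint in enumerate(TIMEPOINTS):
        comp_values = {}
        for comp in COMPONENTS:
            params = scenario.component_params[comp]
            zp = params.zero_prob_array()[t_idx, arm]
            gm = params.gamma_mean_array()[t_idx, arm]
            shape = params.gamma_shape
            positive = rng.uniform(size=n_teachers) >= zp
            draws = rng.gamma(shape, gm / shape, size=n_teachers)
            comp_values[comp] = np.where(positive, draws, 0.0)
        sum3 = sum(comp_values.values())
        target = targets[timepoint]
        # rescale components into the total when they overshoot, so the
        # recorded total follows the Normal total-activity model exactly
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(sum3 > target, np.where(sum3 > 0, target / sum3, 1.0), 1.0)
        for comp in COMPONENTS:
            comp_values[comp] = comp_values[comp] * factor
        sport = np.maximum(target - sum(comp_values.values()), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "school_id": np.array(school_ids)[sc],
                    "teacher_id": teacher_ids,
                    "arm": np.array(ARMS)[arm],
                    "region": [labels[s][0] for s in sc],
                    "geolocation": [labels[s][1] for s in sc],
                    "timepoint": timepoint,
                    "minutes_pe": comp_values["pe"],
                    "minutes_sport": sport,
                    "minutes_energisers": comp_values["energisers"],
                    "minutes_active_lessons": comp_values["active_lessons"],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records["total_minutes"] = records[
        ["minutes_pe", "minutes_sport", "minutes_energisers", "minutes_active_lessons"]
    ].sum(axis=1)
    records["_invalid_injected"] = False

    records = inject_missingness(
        records, scenario.missing_rate_baseline, scenario.missing_rate_followup, seed=miss_seed
    )
    records = inject_invalid(records, scenario.invalid_rate, seed=invalid_seed)
    records.attrs["truth"] = {
        "scenario": scenario,
        "school_ids": school_ids,
        "school_arm": school_arm,
        "u_school": u_school,
        "n_teachers": int(n_teachers),
        "n_invalid_injected": int(records["_invalid_injected"].sum()),
    }
    return records


def _within_school_counter(sc: np.ndarray) -> np.ndarray:
    out = np.zeros_like(sc)
    seen: dict[int, int] = {}
    for i, s in enumerate(sc):
        seen[s] = seen.get(s, 0) + 1
        out[i] = seen[s]
    return out


# ---------------------------------------------------------------------------
# Missingness and invalid-record injection
# ---------------------------------------------------------------------------

_MINUTE_COLS = ["minutes_pe", "minutes_sport", "minutes_energisers", "minutes_active_lessons"]


def inject_missingness(
    records: pd.DataFrame,
    missing_rate_baseline: float,
    missing_rate_followup: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Mask outcome cells completely at random at per-timepoint rates.

    Masked teacher-timepoints keep their identifier/arm/stratum columns; all
    minute columns and the total become missing.
    """
    for name, r in (
        ("missing_rate_baseline", missing_rate_baseline),
        ("missing_rate_followup", missing_rate_followup),
    ):
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    rate = np.where(
        out["timepoint"].to_numpy() == "baseline", missing_rate_baseline, missing_rate_followup
    )
    mask = rng.uniform(size=len(out)) < rate
    out.loc[mask, _MINUTE_COLS] = np.nan
    if "total_minutes" in out.columns:
        out.loc[mask, "total_minutes"] = np.nan
    out.attrs = dict(records.attrs)
    return out


def inject_invalid(records: pd.DataFrame, invalid_rate: float, seed: int = 0) -> pd.DataFrame:
    """Inflate one record per selected school so its weekly total exceeds 250.

    Schools are selected independently with probability ``invalid_rate``
    (mirroring school-level exclusion tallies); within a selected school one
    observed follow-up record (falling back to baseline) is scaled up to a
    total above 250 minutes and flagged via ``_invalid_injected``.
    """
    if not 0.0 <= invalid_rate <= 1.0:
        raise ConfigurationError(f"invalid_rate must be in [0, 1], got {invalid_rate}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    if "_invalid_injected" not in out.columns:
        out["_invalid_injected"] = False
    schools = out["school_id"].unique()
    chosen = schools[rng.uniform(size=len(schools)) < invalid_rate]
    for school in chosen:
        rows = out.index[
            (out["school_id"] == school)
            & (out["timepoint"] == "followup")
            & out["total_minutes"].notna()
        ]
        if len(rows) == 0:
            rows = out.index[(out["school_id"] == school) & out["total_minutes"].notna()]
        if len(rows) == 0:
            continue
        idx = rows[rng.integers(len(rows))]
        new_total = 251.0 + rng.exponential(30.0)
        current = out.loc[idx, "total_minutes"]
        if current > 0:
            out.loc[idx, _MINUTE_COLS] = out.loc[idx, _MINUTE_COLS].astype(float) * (
                new_total / current
            )
        else:
            out.loc[idx, "minutes_pe"] = new_total
        out.loc[idx, "total_minutes"] = out.loc[idx, _MINUTE_COLS].astype(float).sum()
        out.loc[idx, "_invalid_injected"] = True
    out.attrs = dict(records.attrs)
    return out
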