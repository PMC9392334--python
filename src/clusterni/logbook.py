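"""Logbook ingest, validity filtering and analysis-dataset assembly.

Teacher logbooks arrive as one CSV row per teacher-timepoint with the weekly
minutes recorded for each activity component (PE, sport, energisers, active
lessons).  Blank cells are missing values, never zero.  Records whose weekly
total exceeds the validity threshold (250 minutes across the five-day school
week, boundary inclusive: exactly 250 is valid) are excluded before analysis;
all remaining teachers enter the intention-to-treat dataset, with a missing
mask where one timepoint is absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ParseError, ValidationError
from .synthetic import ARMS, COMPONENTS, LOGBOOK_COLUMNS, TIMEPOINTS

__all__ = [
    "read_logbooks",
    "write_logbooks",
    "validity_filter",
    "build_analysis_dataset",
    "AnalysisDataset",
    "descriptive_stats",
    "VALIDITY_THRESHOLD",
]

#: maximum plausible weekly minutes across a five-day school week
VALIDITY_THRESHOLD = 250.0

_MINUTE_COLS = ["minutes_pe", "minutes_sport", "minutes_energisers", "minutes_active_lessons"]


def read_logbooks(path) -> pd.DataFrame:
    """Read logbook CSV records.

    One record per row; blank minute cells become NaN (missing, not zero);
    ``total_minutes`` is derived as the sum over *observed* components, NaN
    when every component is missing.  Malformed rows raise :class:`ParseError`
    with the offending line number; unknown arm/timepoint labels raise
    :class:`ValidationError`.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != LOGBOOK_COLUMNS:
            raise ParseError(f"{path}: line 1: expected header {','.join(LOGBOOK_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(LOGBOOK_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(LOGBOOK_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(LOGBOOK_COLUMNS, (c.strip() for c in row)))
            if rec["arm"] not in ARMS:
                raise ValidationError(f"{path}: line {lineno}: unknown arm label {rec['arm']!r}")
            if rec["timepoint"] not in TIMEPOINTS:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown timepoint label {rec['timepoint']!r}"
                )
            for col in _MINUTE_COLS:
                cell = rec[col]
                if cell == "":
                    rec[col] = np.nan
                else:
                    try:
                        rec[col] = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric value {cell!r} in {col}"
                        ) from None
                    if rec[col] < 0:
                        raise ValidationError(
                            f"{path}: line {lineno}: negative minutes in {col}"
                        )
            rows.append(rec)
    records = pd.DataFrame(rows, columns=LOGBOOK_COLUMNS)
    for col in _MINUTE_COLS:
        records[col] = records[col].astype(float)
    records["total_minutes"] = records[_MINUTE_COLS].sum(axis=1, min_count=1)
    return records


def write_logbooks(records: pd.DataFrame, path) -> None:
    """Write records in the logbook CSV dialect (blank cell = missing)."""
    records[LOGBOOK_COLUMNS].to_csv(path, index=False, na_rep="")


def validity_filter(
    records: pd.DataFrame,
    threshold: float = VALIDITY_THRESHOLD,
    inclusive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (valid, excluded) on the weekly-total rule.

    A record is invalid when its total exceeds ``threshold`` (strictly, when
    ``inclusive`` — the default reading of "no more than 250 minutes" — or at
    and above the threshold otherwise).  Records with no computable total
    (all components missing) pass through as missing-outcome, not invalid.
    Excluded records carry ``exclusion_reason == 'invalid_total'``.
    """
    total = records["total_minutes"] if "total_minutes" in records.columns else records[
        _MINUTE_COLS
    ].sum(axis=1, min_count=1)
    if inclusive:
        bad = total > threshold
    else:
        bad = total >= threshold
    bad = bad.fillna(False)
    excluded = records.loc[bad].copy()
    excluded["exclusion_reason"] = "invalid_total"
    valid = records.loc[~bad].copy()
    valid.attrs = dict(records.attrs)
    return valid, excluded


@dataclass
class AnalysisDataset:
    """Validated, integer-indexed arrays for the outcome models.

    Teacher-level arrays are aligned: entry *i* describes one teacher with a
    dense school code, a 0/1 arm indicator (0 = original, 1 = adapted) and
    baseline/follow-up totals carrying NaN where the outcome is missing.
    ``components`` holds long-format complete-case arrays per hurdle outcome.
    """

    teacher_id: np.ndarray
    school_index: np.ndarray
    arm_indicator: np.ndarray
    baseline: np.ndarray
    followup: np.ndarray
    school_ids: np.ndarray
    school_arm: np.ndarray
    components: dict = field(default_factory=dict)
    exclusion_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_teachers(self) -> int:
        return self.teacher_id.size

    @property
    def n_schools(self) -> int:
        return self.school_ids.size

    def baseline_missing(self) -> np.ndarray:
        return np.isnan(self.baseline)

    def followup_missing(self) -> np.ndarray:
        return np.isnan(self.followup)


def build_analysis_dataset(
    valid_records: pd.DataFrame,
    exclusion_log: pd.DataFrame | None = None,
) -> AnalysisDataset:
    """Assemble the intention-to-treat dataset from validity-filtered records.

    Teachers observed at only one timepoint are retained with the other
    masked missing.  School codes are dense integers, stable under the sorted
    order of school identifiers.  Raises :class:`ConsistencyError` if a
    teacher maps to more than one school or arm.
    """
    rec = valid_records
    per_teacher = rec.groupby("teacher_id").agg(
        n_school=("school_id", "nunique"), n_arm=("arm", "nunique")
    )
    bad = per_teacher[(per_teacher["n_school"] > 1) | (per_teacher["n_arm"] > 1)]
    if len(bad):
        raise ConsistencyError(
            f"teachers mapped to multiple schools/arms: {sorted(bad.index.tolist())}"
        )
    school_arm_tbl = rec[["school_id", "arm"]].drop_duplicates()
    if school_arm_tbl["school_id"].duplicated().any():
        dupes = school_arm_tbl.loc[
            school_arm_tbl["school_id"].duplicated(), "school_id"
        ].tolist()
        raise ConsistencyError(f"schools mapped to multiple arms: {sorted(dupes)}")

    school_ids = np.sort(rec["school_id"].unique())
    school_code = {s: i for i, s in enumerate(school_ids)}
    arm_of_school = dict(zip(school_arm_tbl["school_id"], school_arm_tbl["arm"]))
    school_arm = np.array([ARMS.index(arm_of_school[s]) for s in school_ids])

    wide = rec.pivot_table(
        index="teacher_id", columns="timepoint", values="total_minutes", aggfunc="first"
    )
    teacher_school = rec.groupby("teacher_id")["school_id"].first()
    teacher_ids = np.array(sorted(teacher_school.index))
    sc = np.array([school_code[teacher_school[t]] for t in teacher_ids])
    arm = school_arm[sc]

    def _col(tp: str) -> np.ndarray:
        if tp in wide.columns:
            return np.array([wide.at[t, tp] if t in wide.index else np.nan for t in teacher_ids])
        return np.full(teacher_ids.size, np.nan)

    baseline = _col("baseline")
    followup = _col("followup")

    components: dict[str, pd.DataFrame] = {}
    time_idx = rec["timepoint"].map({"baseline": 0, "followup": 1}).to_numpy()
    for comp in COMPONENTS:
        col = f"minutes_{comp}"
        obs = rec[col].notna().to_numpy()
        components[comp] = pd.DataFrame(
            {
                "y": rec.loc[obs, col].to_numpy(dtype=float),
                "time": time_idx[obs],
                "arm": rec.loc[obs, "arm"].map({"original": 0, "adapted": 1}).to_numpy(),
                "school_index": rec.loc[obs, "school_id"].map(school_code).to_numpy(),
            }
        )

    return AnalysisDataset(
        teacher_id=teacher_ids,
        school_index=sc,
        arm_indicator=arm,
        baseline=baseline,
        followup=followup,
        school_ids=school_ids,
        school_arm=school_arm,
        components=components,
        exclusion_log=(
            exclusion_log if exclusion_log is not None else pd.DataFrame(columns=["exclusion_reason"])
        ),
    )


def descriptive_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Observed mean (SD) and N of each outcome per arm and timepoint."""
    cols = {"total": "total_minutes", **{c: f"minutes_{c}" for c in COMPONENTS}}
    rows = []
    for outcome, col in cols.items():
        for arm in ARMS:
            for tp in TIMEPOINTS:
                sub = records.loc[
                    (records["arm"] == arm) & (records["timepoint"] == tp), col
                ].dropna()
                rows.append(
                    {
                        "outcome": outcome,
                        "arm": arm,
                        "timepoint": tp,
                        "n": len(sub),
                        "mean": sub.mean() if len(sub) else np.nan,
                        "sd": sub.std(ddof=1) if len(sub) > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
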