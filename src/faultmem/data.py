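"""Trial-level change-detection data: CSV schema, exclusion rules, aggregation.

One row per trial.  Exact column schema (UTF-8, '.' decimal separator)::

    participant_id,condition,memory_rake,probe_rake,is_change,response,response_time_s,lag_s

``condition`` is one of control / train_left_right / train_normal_reverse,
``response`` is same / change, ``is_change`` is true / false and must equal
(memory_rake != probe_rake).  Angles are degrees in [0, 360) and must sit on
the stimulus grid; off-grid angles are an error, never snapped (silent
rebinning would corrupt mirror-line diagnostics).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .lattice import CountLattice, TorusLattice

__all__ = [
    "COLUMNS",
    "CONDITIONS",
    "ExclusionCriteria",
    "ExclusionReport",
    "read_trials",
    "write_trials",
    "validate_trials",
    "apply_exclusions",
    "aggregate_counts",
]

COLUMNS = [
    "participant_id",
    "condition",
    "memory_rake",
    "probe_rake",
    "is_change",
    "response",
    "response_time_s",
    "lag_s",
]

CONDITIONS = ("control", "train_left_right", "train_normal_reverse")
RESPONSES = ("same", "change")


class SchemaError(ValueError):
    """Raised when trial data violates the documented schema."""


@dataclass(frozen=True)
class ExclusionCriteria:
    """Trial/participant exclusion thresholds.

    Defaults follow the study protocol: drop trials with animation lag over
    2.5 s or response time over 5 s (strictly greater; boundary values kept),
    then participants left with fewer than 25 trials, then participants below
    60% correct across their original session of 50 trials.
    """

    max_lag_s: float = 2.5
    max_rt_s: float = 5.0
    min_trials_per_participant: int = 25
    min_accuracy: float = 0.60
    accuracy_denominator_trials: int = 50

    def __post_init__(self):
        if min(self.max_lag_s, self.max_rt_s, self.min_trials_per_participant,
               self.accuracy_denominator_trials) <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if not 0 < self.min_accuracy <= 1:
            raise ValueError("min_accuracy must be in (0, 1]")


@dataclass
class ExclusionReport:
    """Per-rule removal counts; removed + retained reconcile with the input."""

    trials_in: int = 0
    participants_in: int = 0
    trials_removed_lag: int = 0
    trials_removed_rt: int = 0
    participants_removed_min_trials: int = 0
    trials_removed_min_trials: int = 0
    participants_removed_accuracy: int = 0
    trials_removed_accuracy: int = 0
    trials_retained: int = 0
    participants_retained: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def validate_trials(df: pd.DataFrame, step: float | None = None) -> pd.DataFrame:
    """Validate a trial table against the schema; returns a typed copy.

    Errors name the first offending row (0-based, excluding the header).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COLUMNS]
    if missing or extra:
        raise SchemaError(f"bad columns: missing={missing}, extra={extra}")
    out = df[COLUMNS].copy().reset_index(drop=True)

    def _fail(mask, msg):
        if mask.any():
            row = int(np.flatnonzero(mask)[0])
            raise SchemaError(f"row {row}: {msg}")

    out["participant_id"] = out["participant_id"].astype(str)
    _fail(~out["condition"].isin(CONDITIONS), "condition outside enum")
    _fail(~out["response"].isin(RESPONSES), "response outside enum")

    for col in ("memory_rake", "probe_rake", "response_time_s", "lag_s"):
        vals = pd.to_numeric(out[col], errors="coerce")
        _fail(vals.isna() | ~np.isfinite(vals), f"unparseable {col}")
        out[col] = vals.astype(float)
    for col in ("memory_rake", "probe_rake"):
        _fail((out[col] < 0) | (out[col] >= 360), f"{col} outside [0, 360)")
        if step is not None:
            off = np.abs(out[col] / step - np.rint(out[col] / step)) > 1e-9
            _fail(off, f"{col} not on the {step:g}-degree stimulus grid")
    _fail(out["response_time_s"] <= 0, "response_time_s must be > 0")
    _fail(out["lag_s"] < 0, "lag_s must be >= 0")

    if out["is_change"].dtype != bool:
        lowered = out["is_change"].astype(str).str.lower()
        _fail(~lowered.isin(["true", "false"]), "is_change not a boolean")
        out["is_change"] = lowered == "true"
    _fail(out["is_change"] != (out["memory_rake"] != out["probe_rake"]),
          "is_change inconsistent with memory/probe angles")
    return out


def read_trials(path, step: float | None = None) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty and list(df.columns) == COLUMNS:
        return validate_trials(df)
    return validate_trials(df, step=step)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a validated trial table; write-then-read round-trips exactly."""
    out = validate_trials(trials).copy()
    out["is_change"] = np.where(out["is_change"], "true", "false")
    out.to_csv(path, index=False)


def apply_exclusions(trials: pd.DataFrame,
                     criteria: ExclusionCriteria = ExclusionCriteria(),
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the four exclusion rules in order; returns kept trials + report.

    Order: (1) lag > max_lag_s, (2) RT > max_rt_s (both strict: boundary
    values are kept), (3) participants with fewer than
    ``min_trials_per_participant`` remaining trials, (4) participants whose
    number of correct responses over the input session, divided by
    ``accuracy_denominator_trials``, falls below ``min_accuracy``
    ("correct" = response matches the change/no-change ground truth).
    """
    df = validate_trials(trials)
    report = ExclusionReport(trials_in=len(df),
                             participants_in=df["participant_id"].nunique())

    correct = (df["response"] == "change") == df["is_change"]
    n_correct_orig = correct.groupby(df["participant_id"]).sum()

    lag_ok = df["lag_s"] <= criteria.max_lag_s
    report.trials_removed_lag = int((~lag_ok).sum())
    df = df[lag_ok]

    rt_ok = df["response_time_s"] <= criteria.max_rt_s
    report.trials_removed_rt = int((~rt_ok).sum())
    df = df[rt_ok]

    remaining = df.groupby("participant_id").size()
    too_few = remaining[remaining < criteria.min_trials_per_participant].index
    report.participants_removed_min_trials = len(too_few)
    report.trials_removed_min_trials = int(remaining.loc[too_few].sum())
    df = df[~df["participant_id"].isin(too_few)]

    present = df["participant_id"].unique()
    acc = n_correct_orig.loc[present] / criteria.accuracy_denominator_trials
    inaccurate = acc[acc < criteria.min_accuracy].index
    report.participants_removed_accuracy = len(inaccurate)
    report.trials_removed_accuracy = int(df["participant_id"].isin(inaccurate).sum())
    df = df[~df["participant_id"].isin(inaccurate)].reset_index(drop=True)

    report.trials_retained = len(df)
    report.participants_retained = df["participant_id"].nunique()
    return df, report


def aggregate_counts(trials: pd.DataFrame, lattice: TorusLattice) -> CountLattice:
    """Aggregate trials onto the lattice: n = presentations, k = 'change' reports.

    Every trial's angles must lie exactly on the lattice grid.
    """
    df = validate_trials(trials, step=lattice.step)
    n = np.zeros((lattice.L, lattice.L), dtype=np.int64)
    k = np.zeros_like(n)
    if len(df):
        xi = lattice.angle_to_index(df["memory_rake"].to_numpy())
        yi = lattice.angle_to_index(df["probe_rake"].to_numpy())
        np.add.at(n, (xi, yi), 1)
        np.add.at(k, (xi, yi), (df["response"] == "change").to_numpy().astype(np.int64))
    return CountLattice(lattice, n, k)
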