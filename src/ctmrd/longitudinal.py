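"""Landmark / longitudinal MRD status, lead time, and clearance trajectories.

Definitions (postoperative, days from surgery):

* **landmark** — the single MRD status at ~1 month after surgery; the window
  is day 30 ± 7 → [23, 37], and when several samples fall inside it the
  earliest wins.  Patients with no in-window sample are ``unsampled`` and
  excluded from landmark analyses (they remain in longitudinal analyses).
* **longitudinal** — positive iff any *eligible* sample is positive, where
  eligible means drawn on or before the recurrence day (monitoring ends at
  recurrence, inclusive); all samples are eligible for non-recurrent
  patients.
* **lead time** — months from the first positive eligible sample to the
  radiological recurrence, floored at 0.
* **DFS** — surgery to first radiologic recurrence, censored at last
  follow-up; **OS** — surgery to death, censored at last follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .caller import MRDCall
from .types import ClinicalRecordRow, ConfigError, days_to_months

LANDMARK_LO = 23
LANDMARK_HI = 37

TRAJECTORY_CATEGORIES = (
    "cleared_durable",
    "cleared_then_regained",
    "persistent_or_rising",
    "never_positive",
    "not_evaluable",
)


@dataclass
class PatientRecord:
    """One patient's clinical timeline joined with their MRD calls."""

    clinical: ClinicalRecordRow
    calls: list[MRDCall] = field(default_factory=list)
    landmark_call: Optional[MRDCall] = None
    landmark_status: str = "unsampled"  # positive | negative | unsampled
    longitudinal_status: str = "negative"
    dfs_days: int = 0
    dfs_event: bool = False
    os_days: int = 0
    os_event: bool = False
    lead_time_months: Optional[float] = None

    @property
    def patient_id(self) -> str:
        return self.clinical.patient_id


def assign_landmark(
    calls: Sequence[MRDCall],
    window_lo_days: int = LANDMARK_LO,
    window_hi_days: int = LANDMARK_HI,
) -> Optional[MRDCall]:
    """Earliest call inside the landmark window, or None (unsampled)."""
    if window_lo_days > window_hi_days:
        raise ConfigError(
            f"landmark window inverted: [{window_lo_days}, {window_hi_days}]"
        )
    for call in sorted(calls, key=lambda c: c.days_from_surgery):
        if window_lo_days <= call.days_from_surgery <= window_hi_days:
            return call
    return None


def eligible_calls(record_or_clinical, calls: Sequence[MRDCall]) -> list[MRDCall]:
    """Calls on or before the recurrence day (all calls if no recurrence)."""
    clinical = getattr(record_or_clinical, "clinical", record_or_clinical)
    rec = clinical.recurrence_day
    out = [c for c in calls if rec is None or c.days_from_surgery <= rec]
    return sorted(out, key=lambda c: c.days_from_surgery)


def longitudinal_status(record: PatientRecord) -> str:
    """Positive iff any eligible call is positive."""
    if not record.calls:
        raise ValueError(
            f"patient {record.patient_id}: no calls, longitudinal status not evaluable"
        )
    elig = eligible_calls(record, record.calls)
    return "positive" if any(c.positive for c in elig) else "negative"


def lead_time(record: PatientRecord) -> Optional[float]:
    """Months from first positive eligible call to recurrence; None when the
    patient did not recur or never turned positive before recurrence."""
    rec = record.clinical.recurrence_day
    if rec is None:
        return None
    positives = [c for c in eligible_calls(record, record.calls) if c.positive]
    if not positives:
        return None
    first = positives[0].days_from_surgery
    return max(0.0, days_to_months(rec - first))


def build_patient_record(
    clinical: ClinicalRecordRow,
    calls: Sequence[MRDCall],
    window_lo_days: int = LANDMARK_LO,
    window_hi_days: int = LANDMARK_HI,
) -> PatientRecord:
    """Derive all per-patient endpoints from the clinical row and the calls."""
    record = PatientRecord(clinical=clinical, calls=sorted(calls, key=lambda c: c.days_from_surgery))
    record.landmark_call = assign_landmark(record.calls, window_lo_days, window_hi_days)
    if record.landmark_call is None:
        record.landmark_status = "unsampled"
    else:
        record.landmark_status = "positive" if record.landmark_call.positive else "negative"
    record.longitudinal_status = longitudinal_status(record) if record.calls else "negative"

    record.dfs_event = clinical.recurrence_day is not None
    record.dfs_days = (
        clinical.recurrence_day if record.dfs_event else clinical.last_followup_day
    )
    record.os_event = clinical.death_day is not None
    record.os_days = clinical.death_day if record.os_event else clinical.last_followup_day
    record.lead_time_months = lead_time(record)
    return record


# ---------------------------------------------------------------------------
# adjuvant-therapy clearance trajectories


@dataclass
class ClearanceTrajectory:
    patient_id: str
    #: positivity (or None = unsampled) per phase, in timeline order
    phase_calls: dict[str, Optional[bool]] = field(default_factory=dict)
    phase_levels: dict[str, float] = field(default_factory=dict)
    category: str = "not_evaluable"


def classify_trajectory(record: PatientRecord) -> ClearanceTrajectory:
    """Categorize the ctDNA course around adjuvant therapy.

    Phases: ``pre_adjuvant`` (before therapy start), ``during_adjuvant``,
    ``post_adjuvant`` (after therapy end, endpoint excluded) and ``endpoint``
    (the last eligible sample: recurrence time point or end of follow-up).
    Decision table, evaluated on the observed phases in timeline order:

    * therapy start/end unknown, no pre-adjuvant sample, or no sample after
      therapy start → ``not_evaluable``
    * no phase ever positive → ``never_positive``
    * last observed phase negative and pre-adjuvant positive →
      ``cleared_durable``
    * last observed phase positive with an intervening negative phase →
      ``cleared_then_regained``
    * positive at the end without ever clearing (levels persist or rise) →
      ``persistent_or_rising``
    * anything else (e.g. positivity only appearing mid-course with a
      negative pre-adjuvant sample) → ``not_evaluable``
    """
    clinical = record.clinical
    traj = ClearanceTrajectory(patient_id=record.patient_id)
    start, end = clinical.adjuvant_start_day, clinical.adjuvant_end_day
    elig = eligible_calls(record, record.calls)
    if start is None or end is None or not elig:
        return traj

    endpoint = elig[-1]
    phases: dict[str, list[MRDCall]] = {
        "pre_adjuvant": [],
        "during_adjuvant": [],
        "post_adjuvant": [],
        "endpoint": [endpoint],
    }
    for c in elig[:-1]:
        if c.days_from_surgery < start:
            phases["pre_adjuvant"].append(c)
        elif c.days_from_surgery <= end:
            phases["during_adjuvant"].append(c)
        else:
            phases["post_adjuvant"].append(c)

    for name, calls in phases.items():
        if calls:
            traj.phase_calls[name] = any(c.positive for c in calls)
            traj.phase_levels[name] = max(c.ctdna_level for c in calls)
        else:
            traj.phase_calls[name] = None

    pre = traj.phase_calls["pre_adjuvant"]
    observed = [
        (name, traj.phase_calls[name])
        for name in ("pre_adjuvant", "during_adjuvant", "post_adjuvant", "endpoint")
        if traj.phase_calls[name] is not None
    ]
    after_pre = [flag for name, flag in observed if name != "pre_adjuvant"]
    if pre is None or not after_pre:
        traj.category = "not_evaluable"
        return traj

    if not any(flag for _, flag in observed):
        traj.category = "never_positive"
        return traj

    last_flag = observed[-1][1]
    if not last_flag:
        traj.category = "cleared_durable" if pre else "not_evaluable"
        return traj
    # last observed phase positive
    if any(not flag for flag in after_pre[:-1]) or (pre is False and True in after_pre):
        # cleared (some negative after therapy began) then positive again
        if any(not flag for flag in after_pre[:-1]):
            traj.category = "cleared_then_regained"
            return traj
        traj.category = "not_evaluable"
        return traj
    traj.category = "persistent_or_rising"
    return traj


# ---------------------------------------------------------------------------
# per-patient export


def records_table(records: Sequence[PatientRecord], trajectories=None) -> pd.DataFrame:
    """Per-patient summary table (landmark/longitudinal status, DFS/OS,
    lead time, trajectory category)."""
    cats = {t.patient_id: t.category for t in (trajectories or [])}
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "stage": r.clinical.stage,
                "landmark_status": r.landmark_status,
                "longitudinal_status": r.longitudinal_status,
                "dfs_days": r.dfs_days,
                "dfs_event": int(r.dfs_event),
                "os_days": r.os_days,
                "os_event": int(r.os_event),
                "lead_time_months": (
                    "" if r.lead_time_months is None else f"{r.lead_time_months:.6g}"
                ),
                "trajectory": cats.get(r.patient_id, ""),
            }
        )
    return pd.DataFrame(rows)
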