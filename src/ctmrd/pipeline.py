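"""End-to-end orchestration: cohort bundle → calls → records → cohort stats.

Thin glue over the other modules so the CLI, the analysis drivers and the
tests all run the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .background import BackgroundModel
from .caller import (
    CallerConfig,
    MRDCall,
    TissueProfile,
    call_sample,
    chip_pbl_evidence,
    germline_keys_from_pbl,
)
from .longitudinal import PatientRecord, build_patient_record, classify_trajectory
from .stats import CompositionTable, ContingencyMetrics, contingency, summarize_composition
from .survival import CoxFit, KMCurve, cox_fit, km_estimate, logrank_test
from .types import CohortBundle, VariantKey


def read_chip_db(path) -> set[VariantKey]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    }


def call_cohort(
    bundle: CohortBundle,
    chip_keys: set[VariantKey],
    background_model: Optional[BackgroundModel],
    config: CallerConfig = CallerConfig(),
) -> dict[str, list[MRDCall]]:
    """Run the MRD caller on every plasma sample of every patient."""
    calls: dict[str, list[MRDCall]] = {}
    for pid, pdata in bundle.patients.items():
        profile = TissueProfile.from_observations(pid, pdata.tissue)
        germline = germline_keys_from_pbl(pdata.pbl)
        pbl_evidence = chip_pbl_evidence(pdata.pbl)
        calls[pid] = [
            call_sample(
                s.observations,
                profile,
                germline,
                chip_keys,
                pbl_evidence,
                background_model,
                config,
                patient_id=pid,
                sample_id=s.sample_id,
                days_from_surgery=s.days_from_surgery,
            )
            for s in pdata.plasma
        ]
    return calls


def build_records(
    bundle: CohortBundle, calls: dict[str, list[MRDCall]]
) -> list[PatientRecord]:
    return [
        build_patient_record(pdata.clinical, calls.get(pid, []))
        for pid, pdata in bundle.patients.items()
    ]


@dataclass
class CohortResult:
    """The cohort-level outputs: contingency, survival fits, composition."""

    landmark: Optional[ContingencyMetrics]
    longitudinal: ContingencyMetrics
    n_landmark: int
    n_longitudinal: int
    lead_times_months: list[float]
    km_by_longitudinal: dict[str, KMCurve]
    logrank_longitudinal: tuple[float, float]
    cox: Optional[CoxFit]
    composition: CompositionTable
    records: list[PatientRecord] = field(repr=False, default_factory=list)

    @property
    def median_lead_time_months(self) -> Optional[float]:
        if not self.lead_times_months:
            return None
        return float(np.median(self.lead_times_months))


def cox_design(records: Sequence[PatientRecord]):
    """Covariate coding for recurrence prediction: non-adenocarcinoma
    histology, ordinal stage (I=1..III=3), lymph-node involvement, and
    longitudinal ctDNA positivity."""
    stage_code = {"0": 1.0, "I": 1.0, "II": 2.0, "III": 3.0}
    X = np.array(
        [
            [
                0.0 if r.clinical.histology == "adenocarcinoma" else 1.0,
                stage_code.get(r.clinical.stage_group, 1.0),
                1.0 if r.clinical.lymph_node_involved else 0.0,
                1.0 if r.longitudinal_status == "positive" else 0.0,
            ]
            for r in records
        ]
    )
    names = ["nonadenocarcinoma", "stage", "lymph_node", "longitudinal_ctdna"]
    return X, names


def analyze_cohort(records: Sequence[PatientRecord], fit_cox: bool = True) -> CohortResult:
    records = list(records)
    sampled = [r for r in records if r.landmark_status != "unsampled"]
    landmark = contingency(sampled, "landmark_status") if sampled else None
    longitudinal = contingency(records, "longitudinal_status")

    lead = [r.lead_time_months for r in records if r.lead_time_months is not None]

    groups: dict[str, KMCurve] = {}
    by_status: dict[str, list[PatientRecord]] = {"positive": [], "negative": []}
    for r in records:
        by_status[r.longitudinal_status].append(r)
    logrank = (0.0, 1.0)
    if all(by_status.values()):
        for status, rs in by_status.items():
            groups[status] = km_estimate([r.dfs_days for r in rs], [r.dfs_event for r in rs])
        logrank = logrank_test(
            [
                ([r.dfs_days for r in rs], [r.dfs_event for r in rs])
                for rs in by_status.values()
            ]
        )

    cox = None
    if fit_cox:
        X, names = cox_design(records)
        times = np.array([r.dfs_days for r in records], dtype=float)
        events = np.array([r.dfs_event for r in records], dtype=bool)
        try:
            cox = cox_fit(X, times, events, names=names, selection="univariate_first")
        except Exception:
            cox = None  # degenerate small cohorts: survival fits stay empty

    return CohortResult(
        landmark=landmark,
        longitudinal=longitudinal,
        n_landmark=len(sampled),
        n_longitudinal=len(records),
        lead_times_months=sorted(lead),
        km_by_longitudinal=groups,
        logrank_longitudinal=logrank,
        cox=cox,
        composition=summarize_composition(records),
        records=records,
    )


def score_calls_against_truth(
    calls: dict[str, list[MRDCall]], truth
) -> ContingencyMetrics:
    """Sample-level caller performance against simulation ground truth.

    A sample is truth-positive when its true ctDNA fraction is > 0.
    """
    truth_by_sample = {(t.patient_id, t.sample_id): t.truth_positive for t in truth.samples}
    tp = fp = fn = tn = 0
    for pid, patient_calls in calls.items():
        for c in patient_calls:
            is_true = truth_by_sample[(pid, c.sample_id)]
            if c.positive and is_true:
                tp += 1
            elif c.positive:
                fp += 1
            elif is_true:
                fn += 1
            else:
                tn += 1
    return ContingencyMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def trajectories(records: Sequence[PatientRecord]):
    return [classify_trajectory(r) for r in records]
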