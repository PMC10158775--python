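#!/usr/bin/env python
"""Landmark and longitudinal MRD status, lead times and trajectories.

Joins the MRD calls with the clinical timelines, assigns landmark (day
30+/-7) and longitudinal status, computes lead times, classifies
adjuvant-therapy clearance trajectories, and writes results/patients.tsv.
"""

from pathlib import Path

from ctmrd import io as ctio
from ctmrd.longitudinal import records_table
from ctmrd.pipeline import build_records, trajectories

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
CALLS = ROOT / "results" / "calls"
OUT = ROOT / "results" / "patients.tsv"


def main() -> None:
    bundle = ctio.read_cohort(COHORT / "manifest.tsv", COHORT / "clinical.tsv")
    flat = ctio.read_call_report(CALLS / "call_variants.tsv", CALLS / "call_summary.tsv")
    calls = {}
    for c in flat:
        calls.setdefault(c.patient_id, []).append(c)
    records = build_records(bundle, calls)
    trajs = trajectories(records)
    table = records_table(records, trajs)
    table.to_csv(OUT, sep="\t", index=False)

    n_land = sum(r.landmark_status != "unsampled" for r in records)
    n_pos = sum(r.longitudinal_status == "positive" for r in records)
    leads = sorted(r.lead_time_months for r in records if r.lead_time_months is not None)
    print(f"{len(records)} patients -> {OUT}")
    print(f"  landmark-evaluable: {n_land}; longitudinally positive: {n_pos}")
    if leads:
        mid = leads[len(leads) // 2]
        print(f"  lead times: n={len(leads)}, median {mid:.1f} months "
              f"(range {leads[0]:.1f}-{leads[-1]:.1f})")
    cats = {}
    for t in trajs:
        cats[t.category] = cats.get(t.category, 0) + 1
    print("  trajectories:", ", ".join(f"{k}: {v}" for k, v in sorted(cats.items())))


if __name__ == "__main__":
    main()
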