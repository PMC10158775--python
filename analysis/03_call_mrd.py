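#!/usr/bin/env python
"""Call MRD on every plasma sample of the working cohort.

Runs the full filter cascade (germline -> population frequency -> depth ->
CHIP -> background test -> support thresholds) and writes per-variant and
per-sample reports under results/calls/, then scores the caller against the
simulation's ground truth.
"""

from pathlib import Path

import pandas as pd

from ctmrd import io as ctio
from ctmrd.background import read_background_model
from ctmrd.pipeline import call_cohort, read_chip_db, score_calls_against_truth
from ctmrd.simulate import GroundTruth, SampleTruth

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
MODEL = ROOT / "results" / "background_model.tsv"
OUT = ROOT / "results" / "calls"


def load_truth() -> GroundTruth:
    truth = GroundTruth()
    df = pd.read_csv(COHORT / "truth_samples.tsv", sep="\t", dtype={"patient_id": str})
    truth.samples = [
        SampleTruth(r.patient_id, r.sample_id, int(r.days_from_surgery),
                    float(r.true_ctdna_fraction))
        for r in df.itertuples(index=False)
    ]
    return truth


def main() -> None:
    bundle = ctio.read_cohort(COHORT / "manifest.tsv", COHORT / "clinical.tsv")
    model = read_background_model(MODEL)
    chip_keys = read_chip_db(COHORT / "chip_db.tsv")
    calls = call_cohort(bundle, chip_keys, model)
    flat = [c for pc in calls.values() for c in pc]
    vpath, spath = ctio.write_call_report(flat, OUT)
    n_pos = sum(c.positive for c in flat)
    print(f"{len(flat)} samples called, {n_pos} positive ({100 * n_pos / len(flat):.1f}%)")
    print(f"reports: {vpath}, {spath}")

    score = score_calls_against_truth(calls, load_truth())
    print(f"vs simulation truth: sensitivity {100 * score.sensitivity:.1f}%, "
          f"specificity {100 * score.specificity:.1f}% "
          f"(tp={score.tp}, fp={score.fp}, fn={score.fn}, tn={score.tn})")


if __name__ == "__main__":
    main()
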