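#!/usr/bin/env python
"""Generate the working synthetic cohort.

Writes a 177-patient cohort (default study conditions: Table-1-like stage
mix, ~4312x plasma depth, 3-6-monthly sampling, 500-sample healthy panel)
under scratch/cohort/, with ground-truth tables for later evaluation.
"""

from pathlib import Path

from ctmrd.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 1


def main() -> None:
    cohort = simulate_cohort(SimulationConfig(), OUT, seed=SEED)
    n_rec = sum(p.clinical.recurrence_day is not None for p in cohort.patients)
    n_samples = sum(len(p.plasma) for p in cohort.patients)
    print(f"cohort written to {OUT}")
    print(f"  patients: {len(cohort.patients)}, recurrences: {n_rec} "
          f"({100 * n_rec / len(cohort.patients):.1f}%)")
    print(f"  plasma samples: {n_samples} ({n_samples / len(cohort.patients):.1f}/patient)")
    print(f"  healthy panel: {cohort.config.n_healthy} samples x {len(cohort.panel)} sites")


if __name__ == "__main__":
    main()
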