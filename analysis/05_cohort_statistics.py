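#!/usr/bin/env python
"""Cohort-level performance and survival analysis.

Computes the landmark/longitudinal contingency metrics, Kaplan-Meier DFS
curves by longitudinal status with the log-rank test, the Cox model with
univariate-first selection, and the mutation-type composition of positive
patients.  Tables go under results/, and the headline numbers are printed.
"""

from pathlib import Path

import pandas as pd

from ctmrd import io as ctio
from ctmrd.pipeline import analyze_cohort, build_records
from ctmrd.stats import percent

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
CALLS = ROOT / "results" / "calls"
OUT = ROOT / "results"


def main() -> None:
    bundle = ctio.read_cohort(COHORT / "manifest.tsv", COHORT / "clinical.tsv")
    flat = ctio.read_call_report(CALLS / "call_variants.tsv", CALLS / "call_summary.tsv")
    calls = {}
    for c in flat:
        calls.setdefault(c.patient_id, []).append(c)
    records = build_records(bundle, calls)
    result = analyze_cohort(records)

    rows = []
    for name, m, n in (
        ("landmark", result.landmark, result.n_landmark),
        ("longitudinal", result.longitudinal, result.n_longitudinal),
    ):
        if m is None:
            continue
        rows.append({
            "analysis": name, "n": n, "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
            "sensitivity_pct": percent(m.sensitivity),
            "specificity_pct": percent(m.specificity),
            "npv_pct": percent(m.npv),
            "recurrence_rate_positive_pct": percent(m.recurrence_rate_positive),
            "recurrence_rate_negative_pct": percent(m.recurrence_rate_negative),
        })
        print(f"{name} (n={n}): sens {rows[-1]['sensitivity_pct']}%, "
              f"spec {rows[-1]['specificity_pct']}%, NPV {rows[-1]['npv_pct']}%")
    pd.DataFrame(rows).to_csv(OUT / "contingency.tsv", sep="\t", index=False)

    km_rows = []
    for status, km in result.km_by_longitudinal.items():
        for t, s, n_r, d in zip(km.times, km.survival, km.n_at_risk, km.n_events):
            km_rows.append({"group": status, "time_days": t, "survival": s,
                            "n_at_risk": n_r, "n_events": d})
    pd.DataFrame(km_rows).to_csv(OUT / "km_dfs_by_longitudinal.tsv", sep="\t", index=False)
    chi2, p = result.logrank_longitudinal
    print(f"log-rank (DFS, longitudinal +/-): chi2 {chi2:.2f}, p {p:.2g}")

    if result.cox is not None:
        cox_rows = [{
            "covariate": c.name, "hazard_ratio": round(c.hazard_ratio, 3),
            "ci95_lo": round(c.ci95_lo, 3), "ci95_hi": round(c.ci95_hi, 3),
            "wald_p": c.wald_p,
        } for c in result.cox.covariates]
        pd.DataFrame(cox_rows).to_csv(OUT / "cox_multivariate.tsv", sep="\t", index=False)
        print("Cox (univariate-screened):",
              ", ".join(f"{r['covariate']} HR {r['hazard_ratio']}" for r in cox_rows),
              f"| excluded: {result.cox.excluded or 'none'}")

    comp = result.composition
    pd.DataFrame([{
        "n_positive_patients": comp.n,
        "tissue_only": comp.n_tissue_only, "private_only": comp.n_private_only,
        "both": comp.n_both,
        "tissue_only_pct": percent(comp.proportions["tissue_only"]),
        "private_only_pct": percent(comp.proportions["private_only"]),
        "both_pct": percent(comp.proportions["both"]),
    }]).to_csv(OUT / "composition.tsv", sep="\t", index=False)
    print(f"composition of {comp.n} positive patients: "
          f"tissue-only {comp.n_tissue_only}, private-only {comp.n_private_only}, "
          f"both {comp.n_both}")
    if result.median_lead_time_months is not None:
        print(f"median lead time: {result.median_lead_time_months:.1f} months")


if __name__ == "__main__":
    main()
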