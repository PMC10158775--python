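# ctmrd — postoperative ctDNA molecular-residual-disease analysis

Circulating tumor DNA (ctDNA) in plasma after curative-intent surgery marks
molecular residual disease (MRD): microscopic tumor burden invisible to CT.
`ctmrd` implements a tumor-informed MRD pipeline for resected lung cancer
on top of a standardized targeted sequencing panel, together with the
longitudinal surveillance logic and cohort analytics needed to evaluate it —
and, because real patient-level MRD data are almost never shareable, a fully
synthetic cohort generator with known ground truth so every stage is
testable end to end.

It is written for bioinformaticians and biostatisticians who work on liquid
biopsy: the variant caller consumes per-sample variant tables (TSV or a VCF
subset), not reads.

## The method

**Calling.** Each plasma variant is classified by exact
`(chrom, pos, ref, alt)` key against the patient's tumor-tissue profile as
*tissue-derived* (seen in tissue) or *ctDNA-private* (plasma-only: tumor
heterogeneity, evolution, or acquired resistance). A fixed filter cascade is
applied, in order: matched-germline removal; population allele frequency
> 1%; positional depth < 300×; clonal-hematopoiesis (CHIP) removal via a
CHIP key database and matched peripheral-blood-leukocyte (PBL) evidence
(≥ 2 high-quality reads); a per-site sequencing-error background test; and
class-specific high-quality support-read thresholds —

| class | annotation | minimum HQ support reads |
|---|---|---|
| tissue-derived | driver | 2 |
| tissue-derived | other | 4 |
| ctDNA-private | hotspot | 4 |
| ctDNA-private | non-hotspot | 8 |

A sample is **MRD-positive** when at least one variant survives every
filter.

**Background test.** A panel of healthy plasma samples defines, per targeted
SNV site, a beta-binomial error model (method-of-moments fit; pooled
fallback for unseen sites). A candidate with support reads *k* at depth *n*
is kept only if the one-sided upper tail
P(X ≥ k | X ~ BetaBinom(n, α, β)) falls below the significance level
(default 0.01).

**Surveillance.** The *landmark* status is the earliest sample in the
day-30 ± 7 window; the *longitudinal* status is positive if any sample up to
and including recurrence is positive. Lead time is the months (days/30.4375)
from the first positive eligible sample to radiologic recurrence.
Disease-free survival (DFS) runs from surgery to first radiologic
recurrence, censored at last follow-up.

**Cohort analytics.** Sensitivity/specificity/NPV and per-arm recurrence
rates from the 2×2 of MRD status vs recurrence; Kaplan–Meier product-limit
curves; the k-group log-rank test; Cox proportional hazards
(Newton–Raphson on the Efron partial likelihood, Wald CIs, and
univariate-first covariate selection at p < 0.05); Mann–Whitney, Student's
t, Pearson χ², Fisher's exact and the paired Wilcoxon signed-rank test.
The survival and rank machinery is implemented from first principles and
cross-checked against lifelines/scipy in the test suite.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_fit_background.py
python analysis/03_call_mrd.py
python analysis/04_landmark_longitudinal.py
python analysis/05_cohort_statistics.py
```

The drivers simulate a 177-patient cohort under the default study
conditions, fit the background from 500 healthy samples, call MRD on every
plasma sample, and analyze the cohort. A representative run prints:

```
577 samples called, 124 positive (21.5%)
vs simulation truth: sensitivity 71.7%, specificity 91.7% (tp=86, fp=38, fn=34, tn=419)
landmark (n=149): sens 47.2%, spec 91.2%, NPV 84.4%
longitudinal (n=177): sens 76.7%, spec 75.4%, NPV 91.0%
log-rank (DFS, longitudinal +/-): chi2 27.62, p 1.5e-07
Cox (univariate-screened): stage HR 2.266, ..., longitudinal_ctdna HR 5.675
median lead time: 4.7 months
```

Reading: of 577 simulated plasma samples, 124 are called MRD-positive; at
the sample level the caller finds 71.7% of truly ctDNA-bearing samples and
stays quiet on 91.7% of the rest. Patients who are ever positive during
surveillance recur far more often (log-rank p ≈ 1.5e-07), longitudinal
ctDNA positivity is the dominant hazard in the Cox model, and positivity
precedes radiologic recurrence by a median ~5 months.

The same stages are exposed as a CLI (`ctmrd simulate | background | call |
cohort`) for use on cohorts in the documented file formats.

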