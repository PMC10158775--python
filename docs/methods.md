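# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic cohort does and does not
emulate.

## MRD calling

The caller is tumor-informed but panel-standardized: plasma is sequenced
with a fixed targeted panel, and the patient's tumor-tissue variant list is
used only to *classify* plasma variants, not to restrict the search space.
Matching is by exact `(chrom, pos, ref, alt)` key; both inputs must share
one indel left-alignment convention, which the package deliberately does not
re-normalize (silent re-normalization would move the keys the tissue
profile was built on). Multi-allelic records should be split upstream; each
alt allele is its own key.

Filters run in a fixed order — germline, population frequency (> 1%),
depth (< 300×), CHIP, background test, support thresholds — so that every
rejected variant has a deterministic "first failing filter" in the report.
Thresholds at the boundary are inclusive (a tissue-derived driver variant
with exactly 2 high-quality reads passes). "High-quality support reads" is
taken as an input column: producing it (base quality ≥ 30, mapping quality
≥ 30) is the upstream pipeline's job, and the synthetic generator emulates
it as a binomial thinning of support reads (retention 0.92).

CHIP removal honors two routes, each independently toggleable: a key
database of known clonal-hematopoiesis variants, and direct evidence in the
matched PBL sample (≥ 2 high-quality alt reads at the same key). Germline
keys are PBL variants at allele fraction ≥ 0.35; PBL variants below that
are treated as candidate CHIP evidence.

The background test is applied to all plasma SNVs of both classes before
the support-threshold stage; indels bypass it because the healthy panel
models SNV error only. Both choices are configurable (`background_classes`,
`background_enabled`).

One known divergence from some commercial MRD assays: a sub-threshold
tissue-derived variant seen at several time points is never rescued;
each sample is called independently.

## Background error model

Per site, the healthy-plasma panel yields pairs (alt reads, depth) across
samples. The beta-binomial is fit by the method of moments: the mean is the
pooled error rate p̂ = Σx/Σn, and the intraclass correlation ρ comes from
the depth-weighted moment S = Σ nᵢ(pᵢ − p̂)² via
E[S] ≈ p̂q̂[(k−1) + ρ(N − Σnᵢ²/N − (k−1))]. The precision a+b = 1/ρ − 1 is
floored at 10 (a flatter beta would make the tail test powerless against
any signal) and capped at the pooled depth (the fit cannot claim more
certainty than the data carry). Sites with zero observed errors, or whose
moment estimate is under-dispersed, degrade to a near-binomial fit with a
0.5-read pseudocount: α = 0.5, β = pooled depth − 0.5.

The test is one-sided (upper tail) because only excess support is evidence
of ctDNA; the default significance level is 0.01. Numerical note: above
precision a+b = 10⁷ the tail is computed as a plain binomial tail — at that
precision the beta-binomial and binomial tails agree far below any test
resolution, while `scipy.stats.betabinom` loses accuracy to cancellation in
`betaln` as a+b grows.

Estimating ρ ≈ 5·10⁻⁵ from a single site at 500 samples × 3000× carries
Monte-Carlo noise larger than the parameter itself; the parameter-recovery
test therefore checks the pooled (fallback) fit across many sites, where
the moment estimator is tight. Per-site fits at realistic panel sizes are
usable but noisy, which the cap/floor above bounds.

There is no trinucleotide-context smoothing and no strand-specific error
model; a site unseen in the panel gets the pooled fallback, which for a
systematically noisy novel site is anti-conservative in principle but is
mitigated by the support-read thresholds downstream.

## Surveillance logic

The landmark window is day 30 ± 7 → [23, 37]; with several in-window
samples the earliest wins (no tie rule is standard; earliest maximizes
consistency with lead-time computation). Patients without an in-window
sample are excluded from landmark analyses but stay in longitudinal
analyses, which mirrors the usual landmark-cohort vs full-cohort
denominators. Samples after the recurrence day are ineligible everywhere
(monitoring ends at recurrence, inclusive). Lead time uses the *first*
positive eligible sample, not a confirmed pair, and is floored at 0.

ctDNA level is summarized per sample as the mean VAF of passing variants
(0 when negative). Clearance trajectories around adjuvant therapy assign
samples to pre/during/post phases by the therapy start/end days, take the
last eligible sample as the endpoint, and categorize by the decision table
in `ctmrd.longitudinal.classify_trajectory`: durable clearance (positive
before, negative ever after), clearance then regain (an intervening
negative phase before a positive endpoint), persistence/rise (positive at
the end without ever clearing), never positive, or not evaluable (missing
therapy dates or phases). Courses whose positivity first appears mid-course
with a negative pre-adjuvant sample are deliberately "not evaluable" rather
than forced into a clearance category.

## Survival and group statistics

Kaplan–Meier, the log-rank test and Cox regression are implemented in the
package rather than delegated, and validated against lifelines, scipy and
permutation/hand-computed oracles in the tests. Conventions: censored
subjects at t remain in the risk set for events at t; the k-group log-rank
uses the (k−1)-dimensional O−E vector with its hypergeometric covariance
(pseudo-inverse for safety); Cox uses Efron's tie correction, Newton
iteration with step-halving (relative acceptance tolerance 1e-10 — near the
optimum the likelihood change is below the float resolution of its
magnitude), Wald 95% CIs on the log scale, and a separation flag when
|β| or its SE exceeds 10. Univariate-first selection fits each covariate
alone and admits those with two-sided p < 0.05; no multiplicity correction
is applied anywhere.

Rank tests (Mann–Whitney, Wilcoxon signed-rank) use exact enumeration
(dynamic programming over doubled mid-ranks, so ties are exact too) up to
n = 25 and a tie-corrected, continuity-corrected normal approximation
above. Fisher's exact test enumerates the full hypergeometric support and
sums probabilities ≤ the observed table's. Pearson's χ² is uncorrected.
Proportions with empty denominators are reported missing, never 0; reported
percentages round half-up to one decimal.

## Synthetic cohort

The generator emulates the study conditions the pipeline targets, with all
randomness flowing from one seeded generator through per-patient spawned
substreams (fixed seed ⇒ byte-identical output, including across
processes):

| parameter | default | rationale |
|---|---|---|
| patients | 177 | cohort size analyzed |
| stage mix I/II/III | 0.503/0.158/0.333 | published baseline table |
| adenocarcinoma | 0.842 | published baseline table |
| recurrence hazards (monthly) | 0.007/0.020/0.042 | gives ≈23% observed recurrence over a ~16-month median follow-up under uniform 2–30-month censoring |
| shedding probability (recurrent) | 0.55/0.70/0.85 by stage | longitudinal detection ≈ 3/4 of recurrences, shedding increasing with stage |
| transient shedding (non-recurrent) | 0.10 | post-surgical ctDNA that clears (decay 0.8/month) — the biological source of false positives |
| mean plasma depth | 4312× (NB, size 20) | reported effective depth |
| panel | 250 SNV sites over a small lung-cancer gene catalogue | counts-only stand-in for a 338-gene panel |
| per-site error | Beta(1, 9999) per sample | ~1e-4 mean with realistic dispersion |
| healthy panel | 500 samples | reported panel scale |
| tissue burden | lognormal(ln 6, 0.8), clipped [1, 48] | median 6, range 1–48 |
| tumor fraction at recurrence | lognormal(ln 0.02, 1.0) | sub-percent VAFs after the ~0.15–0.5 clonality multiplier |
| backward growth | 0.25/month | detectable window ln(f_rec/f_det)/g ≈ 7 months at f_det ≈ 3e-3, putting simulated lead times in the several-month range |
| CHIP prevalence | 0.25 | 1–2 variants at VAF 0.005–0.04, shared plasma/PBL; half the keys also in the CHIP database |
| germline per patient | 3 | population AF 0.02–0.4, present at VAF ~0.5 in plasma and PBL |
| sampling | landmark draw w.p. 0.825, then 3- or 6-month intervals, plus the recurrence-day sample | reported schedule and landmark-cohort fraction |

ctDNA-private variants are tumor subclones excluded from the tissue-profile
draw (Poisson mean 0.8 per shedding patient). A sample's truth label is
"ctDNA present" iff its true tumor fraction is > 0.

What the generator does **not** emulate: read sequences and alignment
artifacts, strand/fragment-level features, trinucleotide error structure,
site-to-site error-rate heterogeneity beyond the shared beta (each site
draws from the same family), PBL sequencing errors (so no spurious
PBL-evidence CHIP hits), brain-only recurrence non-shedding, and any
treatment effect of adjuvant therapy on the hazard. Passing tests on this
cohort therefore demonstrates the *logic* of the pipeline and its
calibration under the stated error model — not clinical performance on
real plasma.

Problem sizes in the tests and the acceptance script (e.g. 150–250 panel
sites, 120–500 healthy samples, 30–177 patients, 10,000 Monte-Carlo draws)
are the package's chosen defaults for fast, reproducible verification; the
generator scales to larger cohorts by configuration.

## Known limitations

* Exact-key matching cannot pair complex/equivalent indel representations;
  inputs must be consistently normalized upstream.
* The fallback background entry pools heterogeneous sites; for a clean site
  it is conservative, for an unusually noisy novel site anti-conservative.
* The Cox engine handles moderate covariate counts (Newton on dense
  matrices); it is not a high-dimensional solver and flags, rather than
  resolves, separation.
* The per-sample MRD call ignores cross-time-point evidence; longitudinal
  aggregation happens only at the status level.
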