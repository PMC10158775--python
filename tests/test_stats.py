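"""Contingency metrics, group tests and mutation-type composition."""

import numpy as np
import pytest
import scipy.stats

from ctmrd.stats import (
    chi_square,
    composition_from_counts,
    contingency,
    fisher_exact,
    from_counts,
    group_tests,
    mann_whitney,
    percent,
    summarize_composition,
    t_test,
    wilcoxon_signed_rank,
)


class TestContingency:
    def test_landmark_printed_counts(self):
        """36 landmark positives (22 recurred) and 110 negatives (16
        recurred) give sensitivity 57.9% and specificity 87.0%."""
        m = from_counts(tp=22, fp=14, fn=16, tn=94)
        assert percent(m.sensitivity) == 57.9
        assert percent(m.specificity) == 87.0
        assert percent(m.recurrence_rate_positive) == 61.1
        assert percent(m.recurrence_rate_negative) == 14.5
        assert m.n == 146

    def test_longitudinal_printed_counts(self):
        m = from_counts(tp=30, fp=25, fn=11, tn=111)
        assert percent(m.sensitivity) == 73.2
        assert percent(m.specificity) == 81.6
        assert percent(m.recurrence_rate_positive) == 54.5
        assert percent(m.recurrence_rate_negative) == 9.0
        assert percent(m.npv) == 91.0
        assert m.n == 177

    def test_all_correct_toy_cohort(self):
        m = from_counts(tp=5, fp=0, fn=0, tn=7)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_undefined_marginals_reported_missing(self):
        m = from_counts(tp=0, fp=0, fn=3, tn=5)
        assert m.ppv is None
        assert percent(m.ppv) is None
        assert m.npv == pytest.approx(5 / 8)

    def test_recount_oracle_on_random_cohort(self, small_records):
        """Metrics equal a naive independent per-patient recount."""
        for field in ("landmark_status", "longitudinal_status"):
            m = contingency(
                [r for r in small_records if getattr(r, field) != "unsampled"], field
            )
            tp = sum(
                1 for r in small_records
                if getattr(r, field) == "positive" and r.dfs_event
            )
            fp = sum(
                1 for r in small_records
                if getattr(r, field) == "positive" and not r.dfs_event
            )
            fn = sum(
                1 for r in small_records
                if getattr(r, field) == "negative" and r.dfs_event
            )
            tn = sum(
                1 for r in small_records
                if getattr(r, field) == "negative" and not r.dfs_event
            )
            assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
            assert m.n == tp + fp + fn + tn

    def test_proportions_in_unit_interval(self, small_result):
        for m in (small_result.landmark, small_result.longitudinal):
            for v in (m.sensitivity, m.specificity, m.ppv, m.npv):
                if v is not None:
                    assert 0.0 <= v <= 1.0


class TestGroupTests:
    def test_fisher_enumeration_matches_scipy(self):
        table = [[3, 1], [1, 3]]
        _, p = fisher_exact(table)
        # independent: full hypergeometric enumeration gives 34/70
        assert p == pytest.approx(34 / 70)
        assert p == pytest.approx(scipy.stats.fisher_exact(table)[1])

    def test_fisher_matches_scipy_on_grid(self):
        for a, b, c, d in [(2, 8, 7, 3), (10, 2, 3, 9), (0, 5, 5, 0), (4, 4, 4, 4)]:
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(scipy.stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-9)

    def test_chi_square_matches_scipy(self):
        table = [[22, 14], [16, 94]]
        stat, p = chi_square(table)
        ref = scipy.stats.chi2_contingency(np.asarray(table), correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_t_test_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        stat, p = t_test(x, y)
        ref = scipy.stats.ttest_ind(x, y, equal_var=True)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_mann_whitney_exact_small_matches_scipy(self):
        x, y = [1.2, 3.4, 0.5, 2.2], [4.5, 6.1, 2.9, 8.0, 5.5]
        _, p = mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_mann_whitney_normal_approx_large(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0.6, 1, 35)
        _, p = mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_wilcoxon_identical_vectors_p_one(self):
        v = [1.0, 2.0, 3.0]
        stat, p = wilcoxon_signed_rank(v, v)
        assert p == 1.0

    def test_wilcoxon_exact_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0.8, 0.5, 12)
        _, p = wilcoxon_signed_rank(x, y)
        ref = scipy.stats.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_wilcoxon_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])

    def test_dispatch(self):
        assert group_tests("fisher_exact", [[3, 1], [1, 3]])[1] == pytest.approx(34 / 70)
        with pytest.raises(ValueError):
            group_tests("anova", [1], [2])

    def test_mann_whitney_null_p_uniform(self):
        """Under the null the p-value distribution is uniform (1,000
        replicates, exact small-sample path)."""
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(1000):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            ps.append(mann_whitney(x, y)[1])
        # exact discrete p-values are super-uniform: P(p <= t) <= t
        for t in (0.05, 0.1, 0.25, 0.5):
            frac = np.mean(np.asarray(ps) <= t)
            assert frac <= t + 3 * np.sqrt(t * (1 - t) / 1000)


class TestComposition:
    def test_printed_split_30_14_11(self):
        table = composition_from_counts(30, 14, 11)
        props = table.proportions
        assert percent(props["tissue_only"]) == 54.5
        assert percent(props["private_only"]) == 25.5
        assert percent(props["both"]) == 20.0
        assert table.n == 55

    def test_single_patient_tissue_only(self, small_records):
        table = composition_from_counts(1, 0, 0)
        assert table.proportions["tissue_only"] == 1.0

    def test_recount_oracle_on_synthetic_cohort(self, small_records):
        """Composition equals a direct recount over passing variants."""
        table = summarize_composition(small_records)
        tissue_only = private_only = both = 0
        for r in small_records:
            if r.longitudinal_status != "positive":
                continue
            classes = set()
            rec_day = r.clinical.recurrence_day
            for c in r.calls:
                if rec_day is not None and c.days_from_surgery > rec_day:
                    continue
                for cv in c.variants:
                    if cv.passing:
                        classes.add(cv.variant_class)
            if classes == {"tissue_derived"}:
                tissue_only += 1
            elif classes == {"ctdna_private"}:
                private_only += 1
            elif classes:
                both += 1
        assert (table.n_tissue_only, table.n_private_only, table.n_both) == (
            tissue_only, private_only, both,
        )
        assert table.n == sum(
            1 for r in small_records if r.longitudinal_status == "positive"
        )

    def test_vaf_summaries_present_for_observed_classes(self, small_records):
        table = summarize_composition(small_records)
        for cls, (med, lo, hi) in table.vaf_summary.items():
            assert 0 <= lo <= med <= hi <= 1
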