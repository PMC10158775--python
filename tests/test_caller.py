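"""Filter cascade, classification, support thresholds, MRD calls."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ctmrd.caller import (
    CTDNA_PRIVATE,
    TISSUE_DERIVED,
    CallerConfig,
    ClassifiedVariant,
    TissueProfile,
    apply_prefilters,
    apply_support_thresholds,
    call_sample,
    classify_variant,
)
from ctmrd.types import VariantObservation

NO_BACKGROUND = CallerConfig(background_enabled=False)


def obs(
    pos=100,
    depth=3000,
    hq=5,
    support=None,
    pop_af=0.0,
    hotspot=False,
    driver=False,
    chrom="chr7",
    ref="C",
    alt="T",
):
    support = hq if support is None else support
    return VariantObservation(
        chrom=chrom, pos=pos, ref=ref, alt=alt, total_depth=depth,
        support_reads=support, hq_support_reads=hq, pop_af=pop_af,
        is_hotspot=hotspot, is_driver=driver, gene="EGFR",
    )


def profile(*keys, patient="P001"):
    return TissueProfile(patient_id=patient, variants={k: (False, False) for k in keys})


# ---------------------------------------------------------------------------
# independent brute-force rule evaluator (kept deliberately naive)


def oracle_passes(
    in_tissue, driver, hotspot, hq, depth, pop_af, in_germline, in_chip_db, pbl_hq
):
    """Plain-English restatement of the published filtering rules."""
    if in_germline:
        return False
    if pop_af > 0.01:
        return False
    if depth < 300:
        return False
    if in_chip_db or pbl_hq >= 2:
        return False
    if in_tissue:
        needed = 2 if driver else 4
    else:
        needed = 4 if hotspot else 8
    return hq >= needed


class TestClassification:
    def test_key_in_tissue_is_tissue_derived(self):
        o = obs()
        assert classify_variant(o, profile(o.key)) == TISSUE_DERIVED

    def test_key_absent_is_private(self):
        assert classify_variant(obs(), profile(("chr1", 5, "A", "G"))) == CTDNA_PRIVATE

    def test_empty_profile_all_private(self):
        assert classify_variant(obs(), profile()) == CTDNA_PRIVATE


class TestPrefilters:
    def test_population_frequency_fail(self):
        verdicts = apply_prefilters(obs(pop_af=0.02), set(), set())
        assert {v.name: v.passed for v in verdicts}["popfreq"] is False

    def test_population_frequency_boundary_inclusive(self):
        verdicts = apply_prefilters(obs(pop_af=0.01), set(), set())
        assert {v.name: v.passed for v in verdicts}["popfreq"] is True

    def test_shallow_depth_fail(self):
        verdicts = apply_prefilters(obs(depth=299), set(), set())
        assert {v.name: v.passed for v in verdicts}["depth"] is False

    def test_germline_key_fail(self):
        o = obs()
        verdicts = apply_prefilters(o, {o.key}, set())
        assert {v.name: v.passed for v in verdicts}["germline"] is False

    def test_pbl_evidence_triggers_chip(self):
        o = obs()
        pbl = [obs(hq=2, depth=1000)]
        verdicts = apply_prefilters(o, set(), set(), pbl)
        assert {v.name: v.passed for v in verdicts}["chip"] is False

    def test_single_pbl_read_not_chip(self):
        o = obs()
        pbl = [obs(hq=1, depth=1000)]
        verdicts = apply_prefilters(o, set(), set(), pbl)
        assert {v.name: v.passed for v in verdicts}["chip"] is True


class TestSupportThresholds:
    @pytest.mark.parametrize(
        "vclass,flag,hq,expected",
        [
            (TISSUE_DERIVED, True, 2, True),   # driver at threshold
            (TISSUE_DERIVED, True, 1, False),
            (TISSUE_DERIVED, False, 4, True),
            (TISSUE_DERIVED, False, 3, False),
            (CTDNA_PRIVATE, True, 4, True),    # hotspot
            (CTDNA_PRIVATE, True, 3, False),
            (CTDNA_PRIVATE, False, 8, True),   # non-hotspot, stringent
            (CTDNA_PRIVATE, False, 7, False),
        ],
    )
    def test_four_way_thresholds(self, vclass, flag, hq, expected):
        o = obs(hq=hq, driver=flag, hotspot=flag)
        verdict = apply_support_thresholds(ClassifiedVariant(o, vclass))
        assert verdict.passed is expected


class TestCallSample:
    def test_all_filtered_sample_is_negative(self):
        o = obs(hq=1, driver=False)  # below every threshold
        call = call_sample([o], profile(), set(), set(), config=NO_BACKGROUND)
        assert not call.positive
        assert call.ctdna_level == 0.0
        assert call.composition == "none"

    def test_one_passing_tissue_variant_tissue_only(self):
        o = obs(hq=6)
        call = call_sample([o], profile(o.key), set(), set(), config=NO_BACKGROUND)
        assert call.positive
        assert call.composition == "tissue_only"
        assert call.ctdna_level == pytest.approx(o.vaf)

    def test_missing_background_model_errors(self):
        with pytest.raises(ValueError, match="background"):
            call_sample([obs()], profile(), set(), set(), config=CallerConfig())

    def test_tissue_flags_copied_onto_matched_observation(self):
        o = obs(hq=2, driver=False)
        prof = TissueProfile("P001", {o.key: (True, False)})  # driver in tissue
        call = call_sample([o], prof, set(), set(), config=NO_BACKGROUND)
        assert call.positive  # threshold 2 applies because tissue says driver

    def test_patient_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_sample([obs()], profile(patient="P002"), set(), set(),
                        config=NO_BACKGROUND, patient_id="P001")


class TestTruthTable:
    def test_cascade_matches_brute_force_on_exhaustive_grid(self):
        """Every cell of (class x flag x hq 0..10 x depth x pop_af x
        germline x chip-db x PBL-reads) agrees with the naive evaluator."""
        o_key = ("chr7", 100, "C", "T")
        grid = itertools.product(
            [True, False],  # in tissue
            [True, False],  # driver/hotspot flag
            range(0, 11),  # hq support
            [250, 3000],  # depth
            [0.0, 0.02],  # pop_af
            [False, True],  # germline membership
            [False, True],  # chip-db membership
            [0, 1, 2],  # matched PBL HQ reads
        )
        for in_tissue, flag, hq, depth, pop_af, in_germ, in_chip, pbl_hq in grid:
            o = obs(hq=hq, depth=depth, pop_af=pop_af, hotspot=flag, driver=flag)
            prof = profile(o_key) if in_tissue else profile()
            germ = {o_key} if in_germ else set()
            chip = {o_key} if in_chip else set()
            pbl = [obs(hq=pbl_hq, support=pbl_hq, depth=1000)] if pbl_hq else []
            call = call_sample([o], prof, germ, chip, pbl, config=NO_BACKGROUND)
            expected = oracle_passes(
                in_tissue, flag, flag, hq, depth, pop_af, in_germ, in_chip, pbl_hq
            )
            assert call.positive is expected, (
                in_tissue, flag, hq, depth, pop_af, in_germ, in_chip, pbl_hq
            )

    def test_first_failing_filter_is_primary_reason(self):
        o = obs(hq=1, depth=250, pop_af=0.05)
        call = call_sample([o], profile(), {o.key}, set(), config=NO_BACKGROUND)
        (cv,) = call.variants
        assert cv.primary_rejection_reason == "germline"  # first in fixed order


class TestProperties:
    @given(
        hq=st.integers(0, 20),
        extra=st.integers(0, 10),
        flag=st.booleans(),
        in_tissue=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_more_hq_support_never_flips_pass_to_fail(self, hq, extra, flag, in_tissue):
        def passing(h):
            o = obs(hq=h, support=h, driver=flag, hotspot=flag)
            prof = profile(o.key) if in_tissue else profile()
            return call_sample([o], prof, set(), set(), config=NO_BACKGROUND).positive

        if passing(hq):
            assert passing(hq + extra)

    def test_composition_partitions_samples(self, small_calls):
        flat = [c for calls in small_calls.values() for c in calls]
        counts = {"tissue_only": 0, "private_only": 0, "both": 0, "none": 0}
        for c in flat:
            counts[c.composition] += 1
        assert sum(counts.values()) == len(flat)
        for c in flat:
            assert c.positive == (c.composition != "none")

    def test_determinism_identical_calls(self, small_bundle, small_cohort, small_model):
        from ctmrd.pipeline import call_cohort

        a = call_cohort(small_bundle, small_cohort.chip_db, small_model)
        b = call_cohort(small_bundle, small_cohort.chip_db, small_model)
        for pid in a:
            for ca, cb in zip(a[pid], b[pid]):
                assert ca.positive == cb.positive
                assert [v.passing for v in ca.variants] == [v.passing for v in cb.variants]
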