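"""Rule-based MRD variant caller for one plasma sample.

The cascade, in fixed order (the first failing filter is a variant's primary
rejection reason):

1. germline      — key present in the patient's matched germline variants
2. popfreq       — population allele frequency > 1%
3. depth         — positional depth < 300x (default, configurable)
4. chip          — clonal hematopoiesis: key in the CHIP database, or seen
                   with >= 2 HQ reads in the matched PBL sample
5. background    — one-sided beta-binomial test against the healthy-plasma
                   panel (SNVs only; indels bypass, the panel models SNVs)
6. support       — class-specific HQ support-read thresholds:
                   tissue-derived driver >= 2, tissue-derived other >= 4,
                   ctDNA-private hotspot >= 4, ctDNA-private non-hotspot >= 8

Variants surviving every filter are "passing"; a sample is MRD-positive when
at least one variant passes.  Classification (tissue-derived vs
ctDNA-private) is exact-key membership in the patient's tumor-tissue
profile; thresholds at the boundary are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .background import BackgroundModel, test_against_background
from .types import ConfigError, VariantKey, VariantObservation

TISSUE_DERIVED = "tissue_derived"
CTDNA_PRIVATE = "ctdna_private"

FILTER_ORDER = ["germline", "popfreq", "depth", "chip", "background", "support"]

SUPPORT_THRESHOLDS = {
    (TISSUE_DERIVED, True): 2,  # tissue-derived driver
    (TISSUE_DERIVED, False): 4,  # tissue-derived non-driver
    (CTDNA_PRIVATE, True): 4,  # private hotspot
    (CTDNA_PRIVATE, False): 8,  # private non-hotspot
}


@dataclass(frozen=True)
class CallerConfig:
    """Tunable thresholds of the filter cascade."""

    min_depth: int = 300
    max_pop_af: float = 0.01
    alpha_level: float = 0.01
    pbl_min_hq_reads: int = 2
    use_chip_db: bool = True
    use_pbl_evidence: bool = True
    #: apply the healthy-panel test to these classes (indels always bypass)
    background_classes: tuple[str, ...] = (TISSUE_DERIVED, CTDNA_PRIVATE)
    background_enabled: bool = True
    thresholds: dict = field(
        default_factory=lambda: dict(SUPPORT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if not (0 < self.alpha_level < 1):
            raise ConfigError("alpha_level must be in (0,1)")


@dataclass(frozen=True)
class TissueProfile:
    """The patient's tumor-tissue variant keys with driver/hotspot flags."""

    patient_id: str
    variants: dict[VariantKey, tuple[bool, bool]]  # key -> (is_driver, is_hotspot)
    panel_name: str = "tissue"

    @classmethod
    def from_observations(
        cls, patient_id: str, observations: Iterable[VariantObservation], panel_name: str = "tissue"
    ) -> "TissueProfile":
        variants = {o.key: (o.is_driver, o.is_hotspot) for o in observations}
        return cls(patient_id=patient_id, variants=variants, panel_name=panel_name)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants


@dataclass(frozen=True)
class FilterVerdict:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ClassifiedVariant:
    observation: VariantObservation
    variant_class: str
    filter_verdicts: list[FilterVerdict] = field(default_factory=list)

    @property
    def passing(self) -> bool:
        return all(v.passed for v in self.filter_verdicts)

    @property
    def primary_rejection_reason(self) -> Optional[str]:
        for v in self.filter_verdicts:
            if not v.passed:
                return v.name
        return None


@dataclass
class MRDCall:
    patient_id: str
    sample_id: str
    days_from_surgery: int
    variants: list[ClassifiedVariant] = field(default_factory=list)

    @property
    def passing_variants(self) -> list[ClassifiedVariant]:
        return [v for v in self.variants if v.passing]

    @property
    def positive(self) -> bool:
        return len(self.passing_variants) > 0

    @property
    def ctdna_level(self) -> float:
        """Mean VAF over passing variants; 0 for a negative call."""
        pv = self.passing_variants
        if not pv:
            return 0.0
        return sum(v.observation.vaf for v in pv) / len(pv)

    @property
    def composition(self) -> str:
        classes = {v.variant_class for v in self.passing_variants}
        if not classes:
            return "none"
        if classes == {TISSUE_DERIVED}:
            return "tissue_only"
        if classes == {CTDNA_PRIVATE}:
            return "private_only"
        return "both"


# ---------------------------------------------------------------------------


def classify_variant(obs: VariantObservation, tissue_profile: TissueProfile) -> str:
    """Tissue-derived iff the exact (chrom,pos,ref,alt) key is in the matched
    tumor-tissue profile; everything else is ctDNA-private."""
    return TISSUE_DERIVED if obs.key in tissue_profile else CTDNA_PRIVATE


def _with_tissue_flags(obs: VariantObservation, profile: TissueProfile) -> VariantObservation:
    """Copy driver/hotspot flags from the tissue profile onto a matched
    plasma observation (tissue annotation is authoritative for its own keys)."""
    flags = profile.variants.get(obs.key)
    if flags is None:
        return obs
    is_driver, is_hotspot = flags
    if obs.is_driver == is_driver and obs.is_hotspot == is_hotspot:
        return obs
    from dataclasses import replace

    return replace(obs, is_driver=obs.is_driver or is_driver, is_hotspot=obs.is_hotspot or is_hotspot)


def apply_prefilters(
    obs: VariantObservation,
    germline_keys: set[VariantKey],
    chip_keys: set[VariantKey],
    pbl_observations: Sequence[VariantObservation] = (),
    config: CallerConfig = CallerConfig(),
) -> list[FilterVerdict]:
    """Ordered verdicts for germline, population-frequency, depth and CHIP."""
    verdicts = []
    in_germline = obs.key in germline_keys
    verdicts.append(
        FilterVerdict("germline", not in_germline, "matched germline variant" if in_germline else "")
    )
    high_af = obs.pop_af > config.max_pop_af
    verdicts.append(
        FilterVerdict(
            "popfreq", not high_af, f"pop_af {obs.pop_af:.4g} > {config.max_pop_af:.4g}" if high_af else ""
        )
    )
    shallow = obs.total_depth < config.min_depth
    verdicts.append(
        FilterVerdict(
            "depth", not shallow, f"depth {obs.total_depth} < {config.min_depth}" if shallow else ""
        )
    )
    chip_db_hit = config.use_chip_db and obs.key in chip_keys
    pbl_hit = False
    if config.use_pbl_evidence:
        for p in pbl_observations:
            if p.key == obs.key and p.hq_support_reads >= config.pbl_min_hq_reads:
                pbl_hit = True
                break
    is_chip = chip_db_hit or pbl_hit
    detail = ""
    if is_chip:
        detail = "CHIP database hit" if chip_db_hit else "PBL evidence"
    verdicts.append(FilterVerdict("chip", not is_chip, detail))
    return verdicts


def support_threshold(variant_class: str, obs: VariantObservation, config: CallerConfig = CallerConfig()) -> int:
    """Class-specific HQ support-read threshold (driver flag decides for
    tissue-derived variants, hotspot flag for ctDNA-private ones)."""
    flag = obs.is_driver if variant_class == TISSUE_DERIVED else obs.is_hotspot
    return config.thresholds[(variant_class, flag)]


def apply_support_thresholds(
    classified: ClassifiedVariant, config: CallerConfig = CallerConfig()
) -> FilterVerdict:
    obs = classified.observation
    thr = support_threshold(classified.variant_class, obs, config)
    passed = obs.hq_support_reads >= thr
    return FilterVerdict(
        "support",
        passed,
        "" if passed else f"hq_support {obs.hq_support_reads} < {thr} ({classified.variant_class})",
    )


def call_sample(
    plasma_obs: Sequence[VariantObservation],
    tissue_profile: TissueProfile,
    germline_keys: set[VariantKey],
    chip_keys: set[VariantKey],
    pbl_obs: Sequence[VariantObservation] = (),
    background_model: Optional[BackgroundModel] = None,
    config: CallerConfig = CallerConfig(),
    patient_id: str = "",
    sample_id: str = "",
    days_from_surgery: int = 0,
) -> MRDCall:
    """Run the full ordered cascade on one plasma sample."""
    patient_id = patient_id or tissue_profile.patient_id
    if patient_id != tissue_profile.patient_id:
        raise ValueError(
            f"tissue profile for {tissue_profile.patient_id!r} used on patient {patient_id!r}"
        )
    needs_background = config.background_enabled and any(o.is_snv for o in plasma_obs)
    if needs_background and background_model is None:
        raise ValueError("SNVs present but no background model (disable the test explicitly to skip)")

    call = MRDCall(patient_id=patient_id, sample_id=sample_id, days_from_surgery=days_from_surgery)
    for raw in plasma_obs:
        obs = _with_tissue_flags(raw, tissue_profile)
        vclass = classify_variant(obs, tissue_profile)
        cv = ClassifiedVariant(observation=obs, variant_class=vclass)
        cv.filter_verdicts = apply_prefilters(
            obs, germline_keys, chip_keys, pbl_obs, config
        )
        if config.background_enabled and obs.is_snv and vclass in config.background_classes:
            p, significant = test_against_background(obs, background_model, config.alpha_level)
            cv.filter_verdicts.append(
                FilterVerdict(
                    "background",
                    significant,
                    f"p={p:.3g}" if significant else f"p={p:.3g} >= alpha {config.alpha_level}",
                )
            )
        else:
            cv.filter_verdicts.append(FilterVerdict("background", True, "bypassed"))
        cv.filter_verdicts.append(apply_support_thresholds(cv, config))
        call.variants.append(cv)
    return call


def germline_keys_from_pbl(
    pbl_obs: Sequence[VariantObservation], min_vaf: float = 0.35
) -> set[VariantKey]:
    """Germline variants are PBL calls near heterozygous/homozygous VAF."""
    return {o.key for o in pbl_obs if o.vaf >= min_vaf}


def chip_pbl_evidence(
    pbl_obs: Sequence[VariantObservation], min_vaf: float = 0.35
) -> list[VariantObservation]:
    """PBL calls below germline VAF: candidate clonal-hematopoiesis evidence."""
    return [o for o in pbl_obs if o.vaf < min_vaf]
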