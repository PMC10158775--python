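"""Core domain types for tumor-informed ctDNA MRD analysis.

The atom of the pipeline is a :class:`VariantObservation` — one candidate
variant in one sequencing material (plasma, tumor tissue, peripheral-blood
leukocytes, or a healthy-plasma panel member), carrying its read support and
annotations.  Coordinates are 1-based, VCF convention; indels are taken as
given in the input (no re-normalization), and plasma/tissue matching is by
exact ``(chrom, pos, ref, alt)`` key, so both inputs must share one
left-alignment convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Fixed days-per-month divisor used everywhere months are reported.
DAYS_PER_MONTH = 30.4375

VariantKey = tuple[str, int, str, str]


class FormatError(ValueError):
    """A malformed input table or file (missing column, bad row)."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class VariantObservation:
    """One observed variant with read support and annotations.

    ``vaf`` is derived as ``support_reads / total_depth`` (0 at zero depth);
    a missing population allele frequency is treated as 0 so that absent
    annotation never discards evidence.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    support_reads: int
    hq_support_reads: int
    pop_af: float = 0.0
    is_hotspot: bool = False
    is_driver: bool = False
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("ref and alt alleles must be nonempty")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not (0 <= self.hq_support_reads <= self.support_reads <= self.total_depth):
            raise FormatError(
                "require 0 <= hq_support_reads <= support_reads <= total_depth, got "
                f"hq={self.hq_support_reads}, support={self.support_reads}, "
                f"depth={self.total_depth} at {self.chrom}:{self.pos}"
            )
        if not (0.0 <= self.pop_af <= 1.0):
            raise FormatError(f"pop_af outside [0,1]: {self.pop_af}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        if self.total_depth == 0:
            return 0.0
        return self.support_reads / self.total_depth

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SampleManifestRow:
    """One row of the sample manifest: which file holds which material."""

    patient_id: str
    sample_id: str
    material: str  # plasma | tissue | pbl | healthy_plasma
    days_from_surgery: Optional[int]
    variant_file: str

    MATERIALS = ("plasma", "tissue", "pbl", "healthy_plasma")

    def __post_init__(self) -> None:
        if self.material not in self.MATERIALS:
            raise FormatError(f"unknown material {self.material!r}")
        if self.material == "plasma":
            if self.days_from_surgery is None or self.days_from_surgery < 0:
                raise FormatError(
                    f"plasma sample {self.sample_id} needs days_from_surgery >= 0 "
                    "(postoperative study)"
                )


@dataclass(frozen=True)
class ClinicalRecordRow:
    """Clinical timeline for one patient, in integer days from surgery."""

    patient_id: str
    stage: str  # 0 | I | II | III, optional substage suffix (e.g. IIIa)
    histology: str
    surgery_day: int = 0
    recurrence_day: Optional[int] = None
    death_day: Optional[int] = None
    last_followup_day: int = 0
    adjuvant: str = "none"  # none | chemo | targeted | chemo_immuno | other
    adjuvant_start_day: Optional[int] = None
    adjuvant_end_day: Optional[int] = None
    lymph_node_involved: bool = False
    smoking: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("recurrence_day", "death_day"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise FormatError(f"{name} must be >= 0, got {v}")
        if self.last_followup_day < 0:
            raise FormatError("last_followup_day must be >= 0")
        if (
            self.recurrence_day is not None
            and self.recurrence_day > self.last_followup_day
        ):
            raise FormatError(
                f"recurrence_day {self.recurrence_day} after last_followup_day "
                f"{self.last_followup_day} for {self.patient_id}"
            )

    @property
    def stage_group(self) -> str:
        """Stage without substage suffix (IIIa -> III)."""
        for g in ("III", "II", "I", "0"):
            if self.stage.startswith(g):
                return g
        return self.stage


@dataclass
class PlasmaSample:
    """One plasma draw: its identifiers and variant observations."""

    patient_id: str
    sample_id: str
    days_from_surgery: int
    observations: list[VariantObservation] = field(default_factory=list)


@dataclass
class PatientData:
    """All raw inputs attached to one patient."""

    clinical: ClinicalRecordRow
    tissue: list[VariantObservation] = field(default_factory=list)
    pbl: list[VariantObservation] = field(default_factory=list)
    plasma: list[PlasmaSample] = field(default_factory=list)


@dataclass
class CohortBundle:
    """A loaded cohort: patients with attached samples and clinical rows."""

    patients: dict[str, PatientData]
    orphan_samples: list[SampleManifestRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.patients.values())

    def __len__(self) -> int:
        return len(self.patients)


def days_to_months(days: float) -> float:
    """Convert days to months with the fixed reporting divisor."""
    return days / DAYS_PER_MONTH
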