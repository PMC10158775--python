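"""Synthetic cohort generator with known ground truth.

Emulates the study conditions the pipeline is built for: a 177-patient-like
resected-lung-cancer cohort with a stage mix of roughly 50/16/33% (I/II/III),
~84% adenocarcinoma, stage-dependent exponential recurrence hazards
calibrated to ≈23% observed recurrence over a ~16-month median follow-up,
ultra-deep plasma sequencing (mean effective depth 4312×) over a fixed
targeted SNV panel, per-site sequencing error with beta-binomial dispersion,
clonal-hematopoiesis variants shared between plasma and PBLs, germline
leak-through at population frequencies > 1%, and 3–6-monthly sampling with a
landmark draw ~1 month after surgery.

Tumor shedding is modeled as a tumor fraction that grows exponentially
backward from recurrence (so detectability windows — and hence simulated
lead times — are controlled by one growth-rate parameter), and decays to
zero for cured patients.  ctDNA-private variants are tumor subclones left
out of the tissue-profile draw.  Counts only: no reads, no alignment
artifacts, no fragmentomics.

All randomness flows from one seeded generator with spawned per-patient
substreams, so a fixed seed gives byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as ctio
from .types import (
    ClinicalRecordRow,
    ConfigError,
    DAYS_PER_MONTH,
    PlasmaSample,
    SampleManifestRow,
    VariantKey,
    VariantObservation,
)

# small bundled lung-cancer gene catalogue used to lay out the panel
PANEL_GENES = [
    "EGFR", "TP53", "KRAS", "LRP1B", "RBM10", "PIK3CA", "SMARCA4", "STK11",
    "ALK", "BRAF", "MET", "ERBB2", "CDKN2A", "KEAP1", "NF1", "ROS1", "RET",
    "CTNNB1", "ARID1A", "ATM", "BRCA2", "FAT1", "KMT2D", "NFE2L2", "PTEN",
]
DRIVER_GENES = {
    "EGFR", "KRAS", "BRAF", "PIK3CA", "ALK", "MET", "ERBB2", "ROS1", "RET", "TP53",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs; defaults are the emulated cohort's conditions."""

    n_patients: int = 177
    stage_probs: tuple[float, float, float] = (0.503, 0.158, 0.333)  # I, II, III
    adeno_prob: float = 0.842
    #: monthly exponential recurrence hazards per stage
    recurrence_hazard: tuple[float, float, float] = (0.007, 0.020, 0.042)
    #: probability that a recurrent tumor sheds detectable ctDNA
    shedding_prob: tuple[float, float, float] = (0.55, 0.70, 0.85)
    #: transient post-surgical shedding in patients who never recur
    nonrecurrent_shed_prob: float = 0.10

    mean_depth: float = 4312.0
    depth_dispersion: float = 20.0  # negative-binomial size parameter
    pbl_depth: float = 1000.0
    tissue_depth: float = 800.0
    hq_frac: float = 0.92  # fraction of support reads passing Q30/MQ30

    n_panel_sites: int = 250
    hotspot_frac: float = 0.08
    driver_site_frac: float = 0.15
    #: per-site, per-sample error fraction ~ Beta(a0, b0)
    background_beta: tuple[float, float] = (1.0, 9999.0)
    n_healthy: int = 500

    #: tumor fraction at recurrence ~ lognormal(mu, sigma); with the default
    #: growth rate this yields a median detectable window of ~7 months
    #: (ln(f_rec / f_detectable) / growth, f_detectable ≈ 3e-3)
    vaf_at_detection: tuple[float, float] = (math.log(0.02), 1.0)
    vaf_growth_per_month: float = 0.25  # backward-exponential growth rate
    cured_decay_per_month: float = 0.8
    tissue_burden_lognorm: tuple[float, float] = (math.log(6.0), 0.8)
    tissue_burden_max: int = 48
    private_mut_mean: float = 0.8  # Poisson mean of private subclonal variants

    chip_prob: float = 0.25
    germline_per_patient: int = 3

    landmark_prob: float = 0.825
    sampling_interval_days: tuple[int, ...] = (91, 182)  # 3 or 6 months
    followup_min_months: float = 2.0
    followup_max_months: float = 30.0

    seed: int = 0

    def validate(self) -> None:
        probs = [*self.stage_probs, self.adeno_prob, self.nonrecurrent_shed_prob,
                 self.chip_prob, self.landmark_prob, self.hq_frac, *self.shedding_prob]
        if any(not (0 <= p <= 1) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if any(r <= 0 for r in self.recurrence_hazard):
            raise ConfigError("recurrence hazards must be > 0")
        if self.n_patients < 1 or self.n_panel_sites < 1 or self.n_healthy < 1:
            raise ConfigError("counts must be >= 1")
        if self.followup_min_months > self.followup_max_months:
            raise ConfigError("follow-up window inverted")


@dataclass(frozen=True)
class PanelSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    is_hotspot: bool
    is_driver: bool

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleTruth:
    patient_id: str
    sample_id: str
    days_from_surgery: int
    true_ctdna_fraction: float

    @property
    def truth_positive(self) -> bool:
        return self.true_ctdna_fraction > 0


@dataclass
class GroundTruth:
    """True labels behind every emitted observation."""

    recurrence_day: dict[str, Optional[int]] = field(default_factory=dict)
    shedding: dict[str, bool] = field(default_factory=dict)
    samples: list[SampleTruth] = field(default_factory=list)
    #: (patient_id, key) -> true class: tumor | tumor_private | germline | chip
    variant_class: dict[tuple[str, VariantKey], str] = field(default_factory=dict)

    def class_of(self, patient_id: str, key: VariantKey) -> str:
        return self.variant_class.get((patient_id, key), "error")


@dataclass
class SimulatedPatient:
    clinical: ClinicalRecordRow
    tissue: list[VariantObservation]
    pbl: list[VariantObservation]
    plasma: list[PlasmaSample]
    sample_truths: list[SampleTruth]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    panel: list[PanelSite]
    patients: list[SimulatedPatient]
    chip_db: set[VariantKey]
    #: long table: sample_id, chrom, pos, ref, alt, total_depth, support_reads
    healthy_panel: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# helpers

BASES = "ACGT"


def _nb_depth(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return np.maximum(1, rng.negative_binomial(size_param, p, size=n))


def _beta_err(rng: np.random.Generator, a0: float, b0: float, size=None):
    """Per-sample error fraction; a0 = 0 is the exact zero-error limit."""
    if a0 <= 0:
        return 0.0 if size is None else np.zeros(size)
    return rng.beta(a0, b0, size=size)


def build_panel(config: SimulationConfig, rng: np.random.Generator) -> list[PanelSite]:
    """A fixed targeted SNV panel laid out over the bundled gene catalogue."""
    sites: list[PanelSite] = []
    used: set[tuple[str, int]] = set()
    while len(sites) < config.n_panel_sites:
        gene = PANEL_GENES[int(rng.integers(len(PANEL_GENES)))]
        # stable across processes (builtin hash() is salted per run)
        digest = sum(ord(ch) * 31**i for i, ch in enumerate(gene))
        chrom = f"chr{1 + digest % 22}"
        pos = int(rng.integers(1_000_000, 50_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        hotspot = bool(rng.random() < config.hotspot_frac)
        driver = hotspot or (gene in DRIVER_GENES and rng.random() < config.driver_site_frac)
        sites.append(
            PanelSite(chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
                      gene=gene, is_hotspot=hotspot, is_driver=driver)
        )
    return sites


def _site_obs(
    site: PanelSite,
    depth: int,
    support: int,
    hq: int,
    pop_af: float = 0.0,
) -> VariantObservation:
    return VariantObservation(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=site.alt,
        total_depth=int(depth),
        support_reads=int(support),
        hq_support_reads=int(hq),
        pop_af=pop_af,
        is_hotspot=site.is_hotspot,
        is_driver=site.is_driver,
        gene=site.gene,
    )


# ---------------------------------------------------------------------------
# per-patient simulation

STAGES = ("I", "II", "III")


def simulate_patient(
    config: SimulationConfig,
    rng: np.random.Generator,
    panel: list[PanelSite],
    patient_id: str,
    truth: GroundTruth,
    chip_db: set[VariantKey],
) -> SimulatedPatient:
    config.validate()
    a0, b0 = config.background_beta
    stage_probs = np.asarray(config.stage_probs, dtype=float)
    stage_probs = stage_probs / stage_probs.sum()
    si = int(rng.choice(3, p=stage_probs))
    stage = STAGES[si]
    adeno = rng.random() < config.adeno_prob
    lymph = rng.random() < (0.15, 0.5, 0.8)[si]

    # outcome: exponential recurrence vs administrative censoring
    censor_m = rng.uniform(config.followup_min_months, config.followup_max_months)
    t_rec_m = rng.exponential(1.0 / config.recurrence_hazard[si])
    recurred = t_rec_m <= censor_m
    recurrence_day = int(round(t_rec_m * DAYS_PER_MONTH)) if recurred else None
    if recurrence_day is not None:
        recurrence_day = max(recurrence_day, 20)  # earliest plausible radiologic call
    last_day = recurrence_day if recurred else int(round(censor_m * DAYS_PER_MONTH))
    last_day = max(last_day, 30)
    death_day = None
    if recurred and rng.random() < 0.15:
        death_day = recurrence_day + int(round(rng.exponential(6.0) * DAYS_PER_MONTH))
        last_day = max(last_day, death_day)

    adjuvant = "none"
    adj_start = adj_end = None
    if si >= 1 or rng.random() < 0.15:  # stage II/III mostly treated
        adjuvant = str(rng.choice(["chemo", "targeted", "chemo_immuno", "other", "none"],
                                  p=[0.35, 0.30, 0.05, 0.05, 0.25]))
    if adjuvant != "none":
        adj_start = int(rng.integers(35, 56))
        adj_end = adj_start + (540 if adjuvant == "targeted" else 120)

    clinical = ClinicalRecordRow(
        patient_id=patient_id,
        stage=stage,
        histology="adenocarcinoma" if adeno else "squamous",
        surgery_day=0,
        recurrence_day=recurrence_day,
        death_day=death_day,
        last_followup_day=last_day,
        adjuvant=adjuvant,
        adjuvant_start_day=adj_start,
        adjuvant_end_day=adj_end,
        lymph_node_involved=bool(lymph),
        smoking=str(rng.choice(["never", "ever"])),
    )

    # --- tumor genotype -------------------------------------------------
    mu, sigma = config.tissue_burden_lognorm
    n_mut = int(np.clip(round(rng.lognormal(mu, sigma)), 1, config.tissue_burden_max))
    n_private = int(rng.poisson(config.private_mut_mean))
    picks = rng.choice(len(panel), size=min(len(panel), n_mut + n_private + config.germline_per_patient + 2),
                       replace=False)
    tissue_sites = [panel[i] for i in picks[:n_mut]]
    private_sites = [panel[i] for i in picks[n_mut : n_mut + n_private]]
    germline_sites = [panel[i] for i in picks[n_mut + n_private : n_mut + n_private + config.germline_per_patient]]
    chip_sites = []
    if rng.random() < config.chip_prob:
        chip_sites = [panel[i] for i in picks[n_mut + n_private + config.germline_per_patient :]][
            : int(rng.integers(1, 3))
        ]

    for s in tissue_sites:
        truth.variant_class[(patient_id, s.key)] = "tumor"
    for s in private_sites:
        truth.variant_class[(patient_id, s.key)] = "tumor_private"
    for s in germline_sites:
        truth.variant_class[(patient_id, s.key)] = "germline"
    for s in chip_sites:
        truth.variant_class[(patient_id, s.key)] = "chip"
        if rng.random() < 0.5:
            chip_db.add(s.key)

    # clonal fraction (as a VAF multiplier on tumor fraction) per tumor variant
    clonal = {s.key: rng.uniform(0.15, 0.5) for s in tissue_sites + private_sites}
    germ_af = {s.key: rng.uniform(0.02, 0.4) for s in germline_sites}
    chip_vaf = {s.key: rng.uniform(0.005, 0.04) for s in chip_sites}

    # --- tissue & PBL observations --------------------------------------
    tissue_obs: list[VariantObservation] = []
    for s in tissue_sites:
        depth = int(_nb_depth(rng, config.tissue_depth, config.depth_dispersion, 1)[0])
        vaf = rng.uniform(0.05, 0.5)
        support = int(rng.binomial(depth, vaf))
        support = max(support, 4)  # tissue calls are confident by construction
        support = min(support, depth)
        hq = int(rng.binomial(support, config.hq_frac))
        tissue_obs.append(_site_obs(s, depth, support, hq))

    pbl_obs: list[VariantObservation] = []
    for s in germline_sites:
        depth = int(_nb_depth(rng, config.pbl_depth, config.depth_dispersion, 1)[0])
        support = int(rng.binomial(depth, 0.5))
        support = max(min(support, depth), 1)
        hq = int(rng.binomial(support, config.hq_frac))
        pbl_obs.append(_site_obs(s, depth, support, hq, pop_af=germ_af[s.key]))
    for s in chip_sites:
        depth = int(_nb_depth(rng, config.pbl_depth, config.depth_dispersion, 1)[0])
        support = int(rng.binomial(depth, chip_vaf[s.key]))
        hq = int(rng.binomial(support, config.hq_frac))
        pbl_obs.append(_site_obs(s, depth, support, hq))

    # --- shedding model --------------------------------------------------
    shedding = False
    f_scale = 0.0
    if recurred:
        shedding = rng.random() < config.shedding_prob[si]
        f_scale = float(rng.lognormal(*config.vaf_at_detection))
    elif rng.random() < config.nonrecurrent_shed_prob:
        shedding = True
        f_scale = float(rng.lognormal(math.log(0.002), 1.0))
    truth.shedding[patient_id] = shedding
    truth.recurrence_day[patient_id] = recurrence_day

    def tumor_fraction(day: int) -> float:
        if not shedding:
            return 0.0
        if recurred:
            months_back = (recurrence_day - day) / DAYS_PER_MONTH
            return f_scale * math.exp(-config.vaf_growth_per_month * max(months_back, 0.0))
        months = day / DAYS_PER_MONTH
        f = f_scale * math.exp(-config.cured_decay_per_month * months)
        return f if f >= 1e-5 else 0.0

    # --- sampling schedule ------------------------------------------------
    days: list[int] = []
    if rng.random() < config.landmark_prob:
        days.append(30 + int(rng.integers(-7, 8)))
    t = 30
    horizon = recurrence_day if recurred else last_day
    while True:
        t += int(rng.choice(config.sampling_interval_days))
        if t >= horizon:
            break
        days.append(t)
    if recurred:
        days.append(recurrence_day)
    days = sorted({max(0, d) for d in days if d <= last_day})
    if not days:
        days = [min(30, last_day)]

    # --- plasma samples ----------------------------------------------------
    plasma: list[PlasmaSample] = []
    sample_truths: list[SampleTruth] = []
    special = (
        [(s, "tumor") for s in tissue_sites]
        + [(s, "tumor") for s in private_sites]
        + [(s, "germline") for s in germline_sites]
        + [(s, "chip") for s in chip_sites]
    )
    special_keys = {s.key for s, _ in special}
    error_sites = [s for s in panel if s.key not in special_keys]

    for i, day in enumerate(days, start=1):
        sid = f"{patient_id}_T{i:02d}"
        f = tumor_fraction(day)
        obs: list[VariantObservation] = []

        depths = _nb_depth(rng, config.mean_depth, config.depth_dispersion, len(special))
        for (s, cls), depth in zip(special, depths):
            err = float(_beta_err(rng, a0, b0))
            if cls == "tumor":
                p = min(1.0, f * clonal[s.key] + err)
                pop_af = 0.0
            elif cls == "germline":
                p = 0.5
                pop_af = germ_af[s.key]
            else:  # chip
                p = min(1.0, chip_vaf[s.key] + err)
                pop_af = 0.0
            support = int(rng.binomial(int(depth), p))
            if support == 0:
                continue
            hq = int(rng.binomial(support, config.hq_frac))
            obs.append(_site_obs(s, int(depth), support, hq, pop_af=pop_af))

        err_depths = _nb_depth(rng, config.mean_depth, config.depth_dispersion, len(error_sites))
        err_p = _beta_err(rng, a0, b0, size=len(error_sites))
        err_support = rng.binomial(err_depths, err_p)
        for s, depth, support in zip(error_sites, err_depths, err_support):
            if support == 0:
                continue
            hq = int(rng.binomial(int(support), config.hq_frac))
            obs.append(_site_obs(s, int(depth), int(support), hq))

        obs.sort(key=lambda o: (o.chrom, o.pos, o.alt))
        plasma.append(
            PlasmaSample(patient_id=patient_id, sample_id=sid, days_from_surgery=day, observations=obs)
        )
        sample_truths.append(
            SampleTruth(patient_id=patient_id, sample_id=sid, days_from_surgery=day,
                        true_ctdna_fraction=f)
        )

    truth.samples.extend(sample_truths)
    return SimulatedPatient(
        clinical=clinical, tissue=tissue_obs, pbl=pbl_obs, plasma=plasma,
        sample_truths=sample_truths,
    )


# ---------------------------------------------------------------------------
# cohort-level simulation


def simulate_healthy_panel(
    config: SimulationConfig, rng: np.random.Generator, panel: list[PanelSite]
) -> pd.DataFrame:
    """Healthy-plasma error panel: per (sample, site) depth and alt count."""
    a0, b0 = config.background_beta
    n, m = config.n_healthy, len(panel)
    depths = _nb_depth(rng, config.mean_depth, config.depth_dispersion, n * m).reshape(n, m)
    p = _beta_err(rng, a0, b0, size=(n, m))
    support = rng.binomial(depths, p)
    rows = {
        "sample_id": np.repeat([f"H{j:04d}" for j in range(n)], m),
        "chrom": np.tile([s.chrom for s in panel], n),
        "pos": np.tile([s.pos for s in panel], n),
        "ref": np.tile([s.ref for s in panel], n),
        "alt": np.tile([s.alt for s in panel], n),
        "total_depth": depths.ravel(),
        "support_reads": support.ravel(),
    }
    return pd.DataFrame(rows)


def simulate_cohort_data(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedCohort:
    """Simulate a full cohort in memory."""
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    root = np.random.default_rng(config.seed)
    panel_rng, healthy_rng, *patient_rngs = root.spawn(2 + config.n_patients)
    panel = build_panel(config, panel_rng)
    truth = GroundTruth()
    chip_db: set[VariantKey] = set()
    patients = [
        simulate_patient(config, patient_rngs[i], panel, f"P{i + 1:03d}", truth, chip_db)
        for i in range(config.n_patients)
    ]
    healthy = simulate_healthy_panel(config, healthy_rng, panel)
    return SimulatedCohort(
        config=config, panel=panel, patients=patients, chip_db=chip_db,
        healthy_panel=healthy, truth=truth,
    )


def simulate_cohort(config: SimulationConfig, out_dir, seed: Optional[int] = None) -> SimulatedCohort:
    """Simulate and write a cohort in the pipeline's file formats.

    Output files: ``manifest.tsv``, ``clinical.tsv``, per-sample variant
    tables under ``variants/``, ``chip_db.tsv``, ``healthy_panel.tsv``,
    ``panel_sites.tsv``, ground-truth tables ``truth_samples.tsv`` /
    ``truth_variants.tsv`` (evaluation only — never read by the caller), and
    a ``README.md`` of realized summary statistics.
    """
    cohort = simulate_cohort_data(config, seed=seed)
    out = Path(out_dir)
    (out / "variants").mkdir(parents=True, exist_ok=True)

    manifest: list[SampleManifestRow] = []
    for p in cohort.patients:
        pid = p.clinical.patient_id
        tf = f"variants/{pid}_tissue.tsv"
        ctio.write_variant_table(p.tissue, out / tf)
        manifest.append(SampleManifestRow(pid, f"{pid}_tissue", "tissue", None, tf))
        bf = f"variants/{pid}_pbl.tsv"
        ctio.write_variant_table(p.pbl, out / bf)
        manifest.append(SampleManifestRow(pid, f"{pid}_pbl", "pbl", None, bf))
        for s in p.plasma:
            vf = f"variants/{s.sample_id}.tsv"
            ctio.write_variant_table(s.observations, out / vf)
            manifest.append(SampleManifestRow(pid, s.sample_id, "plasma", s.days_from_surgery, vf))
    ctio.write_manifest(manifest, out / "manifest.tsv")
    ctio.write_clinical_table([p.clinical for p in cohort.patients], out / "clinical.tsv")

    pd.DataFrame(sorted(cohort.chip_db), columns=["chrom", "pos", "ref", "alt"]).to_csv(
        out / "chip_db.tsv", sep="\t", index=False
    )
    cohort.healthy_panel.to_csv(out / "healthy_panel.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                "gene": s.gene, "is_hotspot": int(s.is_hotspot), "is_driver": int(s.is_driver),
            }
            for s in cohort.panel
        ]
    ).to_csv(out / "panel_sites.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "patient_id": st.patient_id, "sample_id": st.sample_id,
                "days_from_surgery": st.days_from_surgery,
                "true_ctdna_fraction": f"{st.true_ctdna_fraction:.6g}",
            }
            for st in cohort.truth.samples
        ]
    ).to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"patient_id": pid, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "true_class": cls}
            for (pid, k), cls in sorted(cohort.truth.variant_class.items())
        ]
    ).to_csv(out / "truth_variants.tsv", sep="\t", index=False)

    _write_summary(cohort, out / "README.md")
    return cohort


def _write_summary(cohort: SimulatedCohort, path: Path) -> None:
    stages = pd.Series([p.clinical.stage for p in cohort.patients]).value_counts()
    n_rec = sum(p.clinical.recurrence_day is not None for p in cohort.patients)
    n_samples = sum(len(p.plasma) for p in cohort.patients)
    burdens = [len(p.tissue) for p in cohort.patients]
    lines = [
        "# Simulated cohort — realized summary",
        "",
        f"- patients: {len(cohort.patients)} (seed {cohort.config.seed})",
        f"- stage counts: " + ", ".join(f"{s}: {stages.get(s, 0)}" for s in STAGES),
        f"- recurrences: {n_rec} ({100 * n_rec / len(cohort.patients):.1f}%)",
        f"- plasma samples: {n_samples} "
        f"({n_samples / len(cohort.patients):.1f} per patient)",
        f"- tissue mutation burden: median {np.median(burdens):.0f} "
        f"(range {min(burdens)}-{max(burdens)})",
        f"- panel sites: {len(cohort.panel)}; healthy panel: {cohort.config.n_healthy} samples",
        f"- CHIP database keys: {len(cohort.chip_db)}",
        "",
        "Ground-truth files (`truth_*.tsv`) are for evaluation only and are",
        "never read by the caller.",
    ]
    path.write_text("\n".join(lines) + "\n")


def as_bundle(cohort: SimulatedCohort):
    """View a simulated cohort as the bundle the caller consumes (in memory)."""
    from .types import CohortBundle, PatientData

    return CohortBundle(
        patients={
            p.clinical.patient_id: PatientData(
                clinical=p.clinical, tissue=p.tissue, pbl=p.pbl, plasma=p.plasma
            )
            for p in cohort.patients
        }
    )
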