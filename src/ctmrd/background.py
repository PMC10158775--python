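"""Per-site sequencing-error background from a healthy-plasma panel.

Targeted ultra-deep plasma sequencing shows site-specific error rates: some
positions are systematically noisy (context, mapping, oxidative damage), so a
single global error rate misstates the evidence at both clean and noisy
sites.  The model here pools a panel of healthy plasma samples (no tumor
content) per targeted SNV site and fits a beta-binomial by the method of
moments, capturing both the mean error rate and its sample-to-sample
over-dispersion.  A candidate plasma variant is then scored by the one-sided
upper-tail probability of seeing at least its support-read count at its depth
under the fitted site distribution — only excess support is evidence of
ctDNA, so the test is one-sided.

Sites never seen in the panel fall back to one global entry that pools every
panel observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import betabinom, binom

from .types import ConfigError, VariantKey, VariantObservation

FALLBACK_KEY: VariantKey = ("*", 0, "N", "A")

# floor/cap for the fitted precision a+b: below ~10 the beta is so diffuse the
# tail test loses all power; above the pooled panel depth the fit would claim
# more certainty than the data carry.
_MIN_PRECISION = 10.0


@dataclass(frozen=True)
class SiteBackground:
    """Beta-binomial error model at one site."""

    n_panel_samples: int
    pooled_error_rate: float
    alpha_shape: float
    beta_shape: float

    def upper_tail(self, support_reads: int, total_depth: int) -> float:
        """P(X >= support_reads) for X ~ BetaBinom(total_depth, alpha, beta).

        Above precision a+b = 1e7 the beta-binomial is binomial to far below
        test resolution while scipy's betabinom loses accuracy to
        cancellation, so the binomial tail is used there.
        """
        if support_reads <= 0:
            return 1.0
        a, b = self.alpha_shape, self.beta_shape
        if a + b >= 1e7:
            return float(binom.sf(support_reads - 1, total_depth, a / (a + b)))
        return float(betabinom.sf(support_reads - 1, total_depth, a, b))


@dataclass
class BackgroundModel:
    """Per-site error models keyed by (chrom, pos, ref, alt), plus fallback."""

    sites: dict[VariantKey, SiteBackground] = field(default_factory=dict)
    fallback: SiteBackground = None  # type: ignore[assignment]
    panel_size: int = 0

    def lookup(self, key: VariantKey) -> SiteBackground:
        return self.sites.get(key, self.fallback)


def _fit_beta_binomial(support: np.ndarray, depth: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments beta-binomial fit for unequal depths.

    Returns (pooled_rate, alpha, beta).  The intraclass correlation rho is
    estimated from the depth-weighted moment of the per-sample fractions
    (Kleinman-style); zero-error or under-dispersed sites degrade gracefully
    to a near-binomial fit with a 0.5-read pseudocount on the error total.
    """
    support = np.asarray(support, dtype=float)
    depth = np.asarray(depth, dtype=float)
    keep = depth > 0
    support, depth = support[keep], depth[keep]
    if depth.size == 0:
        raise ValueError("no covered panel observations at site")
    total_depth = depth.sum()
    total_err = support.sum()
    p = total_err / total_depth
    k = depth.size

    def pseudo_fit() -> tuple[float, float, float]:
        # near-binomial: precision = pooled depth, 0.5-read pseudocount if clean
        err = total_err if total_err > 0 else 0.5
        a = err
        b = max(total_depth - err, 1.0)
        return (err / total_depth, a, b)

    if total_err == 0 or k < 2 or p >= 1:
        return pseudo_fit()

    frac = support / depth
    s = float(np.sum(depth * (frac - p) ** 2))
    # E[S] ~= p q [ (k-1) + rho (N - sum n^2/N - (k-1)) ]
    denom = total_depth - float(np.sum(depth**2)) / total_depth - (k - 1)
    if denom <= 0:
        return pseudo_fit()
    rho = (s / (p * (1 - p)) - (k - 1)) / denom
    if rho <= 0:
        return pseudo_fit()
    precision = 1.0 / rho - 1.0
    precision = float(np.clip(precision, _MIN_PRECISION, total_depth))
    return (p, p * precision, (1 - p) * precision)


def build_background(
    healthy_observations: Mapping[VariantKey, tuple[Sequence[int], Sequence[int]]],
    min_panel_depth: int = 1000,
    panel_size: int | None = None,
) -> BackgroundModel:
    """Fit the background model from per-site panel observations.

    Parameters
    ----------
    healthy_observations
        Mapping ``(chrom,pos,ref,alt) -> (support_reads, depths)``, the
        per-panel-sample alt counts and depths at that site (equal length,
        zeros included — the panel's clean samples are evidence too).
    min_panel_depth
        Sites whose summed panel depth is below this are dropped (they fall
        back to the global entry at test time).
    panel_size
        Number of healthy samples in the panel; inferred from the longest
        per-site vector when omitted.
    """
    if min_panel_depth < 1:
        raise ConfigError(f"min_panel_depth must be >= 1, got {min_panel_depth}")
    if not healthy_observations:
        raise ValueError("empty healthy panel")

    sites: dict[VariantKey, SiteBackground] = {}
    all_support: list[np.ndarray] = []
    all_depth: list[np.ndarray] = []
    n_max = 0
    for key, (support, depth) in healthy_observations.items():
        support = np.asarray(support, dtype=np.int64)
        depth = np.asarray(depth, dtype=np.int64)
        if support.shape != depth.shape:
            raise ValueError(f"site {key}: support/depth length mismatch")
        n_max = max(n_max, int(depth.size))
        all_support.append(support)
        all_depth.append(depth)
        if depth.sum() < min_panel_depth:
            continue
        rate, a, b = _fit_beta_binomial(support, depth)
        sites[key] = SiteBackground(
            n_panel_samples=int((depth > 0).sum()),
            pooled_error_rate=rate,
            alpha_shape=a,
            beta_shape=b,
        )

    pooled_support = np.concatenate(all_support)
    pooled_depth = np.concatenate(all_depth)
    rate, a, b = _fit_beta_binomial(pooled_support, pooled_depth)
    fallback = SiteBackground(
        n_panel_samples=int((pooled_depth > 0).sum()),
        pooled_error_rate=rate,
        alpha_shape=a,
        beta_shape=b,
    )
    return BackgroundModel(
        sites=sites, fallback=fallback, panel_size=panel_size if panel_size else n_max
    )


def build_background_from_frame(
    panel: pd.DataFrame, min_panel_depth: int = 1000
) -> BackgroundModel:
    """Build from a long table with columns
    sample_id, chrom, pos, ref, alt, total_depth, support_reads."""
    required = {"sample_id", "chrom", "pos", "ref", "alt", "total_depth", "support_reads"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    obs: dict[VariantKey, tuple[list[int], list[int]]] = {}
    for (chrom, pos, ref, alt), grp in panel.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        key = (str(chrom), int(pos), str(ref), str(alt))
        obs[key] = (grp["support_reads"].tolist(), grp["total_depth"].tolist())
    return build_background(
        obs, min_panel_depth=min_panel_depth, panel_size=panel["sample_id"].nunique()
    )


def test_against_background(
    obs: VariantObservation, model: BackgroundModel, alpha_level: float = 0.01
) -> tuple[float, bool]:
    """One-sided test of a plasma observation against the site background.

    Returns ``(p_value, significant)`` where the p-value is the beta-binomial
    upper tail P(X >= support_reads | depth) at the site (fallback entry when
    the site was never covered in the panel) and significance means
    ``p_value < alpha_level``.
    """
    if not (0 < alpha_level < 1):
        raise ConfigError(f"alpha_level must be in (0,1), got {alpha_level}")
    if obs.total_depth <= 0:
        raise ValueError("test_against_background requires total_depth > 0")
    site = model.lookup(obs.key)
    p = site.upper_tail(obs.support_reads, obs.total_depth)
    return p, p < alpha_level


# ---------------------------------------------------------------------------
# serialization (TSV; one reserved '*' row for the fallback entry)

MODEL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "n_panel_samples",
    "pooled_error_rate",
    "alpha_shape",
    "beta_shape",
]


def write_background_model(model: BackgroundModel, path) -> None:
    rows = []
    for key in sorted(model.sites):
        s = model.sites[key]
        rows.append(dict(zip(MODEL_COLUMNS, (*key, s.n_panel_samples, s.pooled_error_rate, s.alpha_shape, s.beta_shape))))
    f = model.fallback
    rows.append(
        dict(zip(MODEL_COLUMNS, (*FALLBACK_KEY, f.n_panel_samples, f.pooled_error_rate, f.alpha_shape, f.beta_shape)))
    )
    df = pd.DataFrame(rows, columns=MODEL_COLUMNS)
    df.loc[df.index[-1], "panel_size"] = model.panel_size
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_background_model(path) -> BackgroundModel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    sites: dict[VariantKey, SiteBackground] = {}
    fallback = None
    panel_size = 0
    for _, r in df.iterrows():
        entry = SiteBackground(
            n_panel_samples=int(r["n_panel_samples"]),
            pooled_error_rate=float(r["pooled_error_rate"]),
            alpha_shape=float(r["alpha_shape"]),
            beta_shape=float(r["beta_shape"]),
        )
        key = (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
        if key == FALLBACK_KEY:
            fallback = entry
            if "panel_size" in df.columns and not pd.isna(r.get("panel_size")):
                panel_size = int(r["panel_size"])
        else:
            sites[key] = entry
    if fallback is None:
        raise ValueError(f"{path}: background model has no fallback row")
    return BackgroundModel(sites=sites, fallback=fallback, panel_size=panel_size)
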