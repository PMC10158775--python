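#!/usr/bin/env python
"""Fit the per-site sequencing-error background from the healthy panel.

Reads scratch/cohort/healthy_panel.tsv, fits the beta-binomial background
(method of moments per site, pooled fallback) and writes
results/background_model.tsv.
"""

from pathlib import Path

import pandas as pd

from ctmrd.background import build_background_from_frame, write_background_model

ROOT = Path(__file__).resolve().parent.parent
PANEL = ROOT / "scratch" / "cohort" / "healthy_panel.tsv"
OUT = ROOT / "results" / "background_model.tsv"


def main() -> None:
    panel = pd.read_csv(PANEL, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    model = build_background_from_frame(panel, min_panel_depth=1000)
    OUT.parent.mkdir(exist_ok=True)
    write_background_model(model, OUT)
    f = model.fallback
    print(f"fit {len(model.sites)} sites from {model.panel_size} healthy samples -> {OUT}")
    print(f"  pooled error rate {f.pooled_error_rate:.3g} "
          f"(alpha {f.alpha_shape:.3g}, beta {f.beta_shape:.4g})")


if __name__ == "__main__":
    main()
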