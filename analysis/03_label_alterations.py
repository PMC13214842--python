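#!/usr/bin/env python
"""Derive demographically adjusted impairment labels and composites.

Fits the normative expected-score OLS (age, education, gender) on the
normative sample, z-scores the primary cohort, binarizes per-test
alteration (|z| > 1 with the TMT direction reversed), applies the MoCA
< 26 cutoff, and builds the five domain composites plus the global
composite. Writes the label table and prints the altered percentages.
"""

from pathlib import Path

import pandas as pd

import oculocog.cohort as sc
from oculocog.config import CohortConfig
from oculocog.normative import COMPOSITES, fit_normative, label_cohort

OUT = Path("results/analysis")
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    normative, primary = sc.generate_cohort(cfg)
    model = fit_normative(normative)
    model.to_json(OUT / "normative_model.json")
    labels = label_cohort(model, primary)
    labels.to_csv(OUT / "labels.csv", index=False)

    flag_cols = sc.NON_MOCA_TESTS + ["moca_altered"] + list(COMPOSITES) + ["global"]
    pct = (labels[flag_cols].mean() * 100).round(2)
    print(f"percent altered participants (n={len(labels)}):")
    print(pct.to_string())


if __name__ == "__main__":
    main()
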