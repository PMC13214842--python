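#!/usr/bin/env python
"""Simulate the study cohorts and example gaze recordings.

Generates the normative (n=133) and primary (n=172) cohorts with the
default demographic and effect-size configuration, writes them under
results/, and synthesizes example raw traces (at 250 Hz to keep the
archive small) for the first few participants so the downstream scripts
have concrete inputs to show.
"""

from pathlib import Path

import oculocog.cohort as sc
from oculocog.config import CohortConfig, default_task_specs
from oculocog.containers import events_to_frame

OUT = Path("results/analysis")
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    normative, primary = sc.generate_cohort(cfg)
    normative.to_csv(OUT / "cohort_normative.csv", index=False)
    primary.to_csv(OUT / "cohort_primary.csv", index=False)
    print(f"primary cohort: n={len(primary)}, age {primary.age.mean():.2f} "
          f"+/- {primary.age.std():.2f}, "
          f"{(primary.gender == 'female').mean():.0%} female")
    print(f"normative sample: n={len(normative)}")

    specs = default_task_specs(sample_rate=250.0)
    trace_dir = Path("scratch/example_traces")  # raw traces are bulky
    trace_dir.mkdir(exist_ok=True)
    for i, row in enumerate(primary.head(3).itertuples(index=False)):
        noise = sc.participant_noise_params(
            primary.iloc[i], cfg, seed=SEED + i
        )
        for task, spec in specs.items():
            rec, target, truth = sc.generate_trace(None, spec, noise[task], SEED + 31 * i)
            rec.to_csv(trace_dir / f"{row.participant_id}_{task}.csv")
            if truth.saccades:
                events_to_frame(truth.saccades).to_csv(
                    trace_dir / f"{row.participant_id}_{task}_events.csv", index=False
                )
    print(f"wrote example traces for 3 participants -> {trace_dir}")


if __name__ == "__main__":
    main()
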