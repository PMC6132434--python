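#!/usr/bin/env python
"""Simulate a multi-study youth cohort and its raw accelerometer streams.

Draws a 13-study cohort whose age-group behaviour distributions follow the
pooled ICAD calibration, plants the published waist-circumference
substitution effects, and realises each person's days as 60-s epoch count
streams.  Writes the phenotype table to results/ and the (large) epoch
stream to scratch/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SCRATCH, SEED, sim_config

from isosub import epochs, io, models, simulate


def main() -> None:
    cfg = sim_config()
    print(f"simulating {cfg.n_studies} studies x {cfg.persons_per_study} persons "
          f"(seed {cfg.seed}) ...")
    cohort = simulate.simulate_cohort(cfg)
    with_outcomes = simulate.simulate_outcomes(cohort, cfg)

    print("\nbehaviour means by age group (simulated, min/day):")
    print(cohort.groupby("age_group")[["sed", "lpa", "mvpa", "wear"]]
          .mean().round(1).to_string())

    plans = simulate.plan_days(cohort, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    by_person: dict[str, list] = {}
    for p in plans:
        by_person.setdefault(p.person_id, []).append(p)
    streams = [simulate.realize_person_stream(pl, seed=rng)
               for pl in by_person.values()]

    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    epochs.write_epoch_stream(streams, SCRATCH / "epoch_stream.csv")
    cols = io.PHENOTYPE_COLUMNS + [o for o in models.OUTCOMES
                                   if o in with_outcomes.columns]
    with_outcomes[cols].to_csv(RESULTS / "phenotypes.csv", index=False)

    n_epochs = sum(len(s) for s in streams)
    print(f"\nwrote {len(streams)} person streams ({n_epochs:,} epochs) to "
          f"{SCRATCH / 'epoch_stream.csv'}")
    print(f"wrote phenotypes for {len(with_outcomes)} persons to "
          f"{RESULTS / 'phenotypes.csv'}")


if __name__ == "__main__":
    main()
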