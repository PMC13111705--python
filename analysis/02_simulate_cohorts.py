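#!/usr/bin/env python
"""Simulate the two synthetic behavioural cohorts.

Generates 60 participants × 52 equal-validity scenarios and 50 × 72
varying-accuracy scenarios from the generative social influence model at
the published cohort-level estimates, and writes the long-format trial
CSVs (plus metadata sidecars) under results/.
"""

from pathlib import Path

from bsim.io import write_trials
from bsim.rosters import load_roster
from bsim.simulate import STUDY1_PARAMS, STUDY2_PARAMS, simulate_cohort

OUT = Path("results")
SEED1, SEED2 = 11, 22


def main():
    OUT.mkdir(exist_ok=True)
    for name, params, n, seed in (
        ("study1", STUDY1_PARAMS, 60, SEED1),
        ("study2", STUDY2_PARAMS, 50, SEED2),
    ):
        roster = load_roster(name)
        cohort = simulate_cohort(n, params, roster, seed=seed)
        path = OUT / f"{name}_cohort.csv"
        write_trials(cohort, path)
        share_a = (cohort["choice"] == "A").mean()
        print(
            f"{name}: {n} participants x {len(roster)} scenarios = "
            f"{len(cohort)} trials (seed {seed}) -> {path}"
        )
        print(
            f"  choice A share {share_a:.3f}, "
            f"mean confidence {cohort['confidence'].mean():.1f}%"
        )


if __name__ == "__main__":
    main()
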