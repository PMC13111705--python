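#!/usr/bin/env python
"""Descriptive analyses: influence curves, normative comparison, ceiling.

Reports, per cohort, (i) choice and confidence in the most likely
diagnosis by posterior level, (ii) the human-vs-AI normative comparison
on corroboration trials (GEE for choices, mixed model for confidence),
and (iii) ceiling diagnostics of the confidence scale at the top
posterior level.  Writes tidy tables under results/.
"""

from pathlib import Path

from bsim.descriptives import (
    ceiling_diagnostics,
    curve_by_posterior,
    normative_comparison,
    select_normative_trials,
)
from bsim.design import Direction, MostLikely
from bsim.influence import confidence_for_option
from bsim.io import read_trials
from bsim.rosters import load_roster

OUT = Path("results")


def main():
    for name in ("study1", "study2"):
        roster = load_roster(name)
        trials = read_trials(OUT / f"{name}_cohort.csv", roster)
        curve = curve_by_posterior(trials, roster)
        print(f"\n{name} informational influence curve:")
        print(curve.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
        curve.to_csv(OUT / f"{name}_curve.csv", index=False)

        subset = select_normative_trials(trials, roster)
        table = normative_comparison(subset, roster)
        pooled = table[table["level"] == "pooled"]
        print(f"normative comparison ({len(subset)} corroboration trials):")
        for _, row in pooled.iterrows():
            print(f"  {row['outcome']:>10}: b = {row['estimate']:+.3f} "
                  f"(SE {row['se']:.3f}, p {row['p']:.4f})")
        table.to_csv(OUT / f"{name}_normative.csv", index=False)

        # ceiling diagnostics at the top posterior level
        by_id = {s.id: s for s in roster}
        top = curve["level"].max()
        conf = []
        for sid, choice, c in zip(trials["scenario_id"], trials["choice"],
                                  trials["confidence"]):
            scen = by_id[sid]
            if scen.posterior_level != top:
                continue
            ml = scen.most_likely
            target = Direction.A if ml is MostLikely.TIE else Direction(ml.value)
            conf.append(confidence_for_option(choice, c, target) / 100.0)
        diag = ceiling_diagnostics(conf)
        print(f"ceiling at level {top:.2f}: skew {diag.skewness:.2f}, "
              f"excess kurtosis {diag.excess_kurtosis:.2f}, top-decile share "
              f"{diag.top_decile_share:.2f} -> "
              + ("SATURATED" if diag.saturated else "not saturated"))


if __name__ == "__main__":
    main()
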