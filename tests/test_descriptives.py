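"""Descriptive analyses: curves, normative selection, ceiling, majority."""

import numpy as np
import pandas as pd
import pytest

from bsim.descriptives import (
    ceiling_diagnostics,
    curve_by_posterior,
    majority_anova,
    majority_models,
    normative_comparison,
    select_normative_trials,
)
from bsim.design import Direction
from bsim.simulate import ParticipantParams, simulate_cohort


def _ideal_cohort(roster, n=10, seed=0):
    params = ParticipantParams(
        beta_bias=0.0, beta_pi=1.0, beta_h=1.0, beta_ai=1.0, sigma_eps=1e-6
    )
    return simulate_cohort(n, params, roster, seed=seed)


class TestCurveByPosterior:
    def test_ideal_bayesian_curve(self, roster1):
        df = _ideal_cohort(roster1)
        curve = curve_by_posterior(df, roster1)
        assert list(curve["level"]) == [0.5, 0.67, 0.80, 0.89]
        above = curve[curve["level"] > 0.5]
        assert (above["choice_mean"] == 1.0).all()
        for _, row in above.iterrows():
            assert row["conf_mean"] == pytest.approx(row["level"], abs=0.01)

    def test_coin_flip_cohort_near_half(self, roster1):
        rng = np.random.default_rng(4)
        rows = [
            (f"p{p}", s.id, rng.choice(["A", "S"]), 50)
            for p in range(30)
            for s in roster1
        ]
        df = pd.DataFrame(
            rows, columns=["participant_id", "scenario_id", "choice", "confidence"]
        )
        curve = curve_by_posterior(df, roster1)
        assert (curve["choice_mean"] - 0.5).abs().max() < 0.07

    def test_participant_first_aggregation_on_unbalanced_data(self, roster1):
        # one heavy participant always wrong, many light ones always right:
        # trial pooling and participant-first aggregation must disagree,
        # and the module must report the participant-first value
        level80 = [s for s in roster1 if s.posterior_level == 0.80]
        rows = []
        for s in level80:
            target = s.most_likely.value
            wrong = "A" if target == "S" else "S"
            rows.append(("heavy", s.id, wrong, 60))
        s0 = level80[0]
        for p in range(3):
            rows.append((f"light{p}", s0.id, s0.most_likely.value, 60))
        df = pd.DataFrame(
            rows, columns=["participant_id", "scenario_id", "choice", "confidence"]
        )
        curve = curve_by_posterior(df, roster1)
        row = curve[curve["level"] == 0.80].iloc[0]
        pooled = np.mean([r[2] == "A" for r in rows])  # not what we want
        assert row["choice_mean"] == pytest.approx(3 / 4)  # participant-first
        assert row["choice_mean"] != pytest.approx(pooled)


class TestNormativeSelection:
    def test_rules_on_roster(self, roster1, cohort1):
        sub = select_normative_trials(cohort1, roster1)
        ids = {s.id: s for s in roster1}
        for sid in sub["scenario_id"].unique():
            scen = ids[sid]
            pi_dir = scen.private.direction
            kinds = {a.kind.value for a in scen.advisors}
            dirs_by_kind = {
                k: {a.direction for a in scen.advisors if a.kind.value == k}
                for k in kinds
            }
            # the corroborating type's advisors all agree with the symptom
            # and no trial has humans and AI sharing a diagnosis
            if len(kinds) == 2:
                assert dirs_by_kind["human"] != dirs_by_kind["ai"]
            assert any(pi_dir in d for d in dirs_by_kind.values())

    def test_idempotent(self, roster1, cohort1):
        once = select_normative_trials(cohort1, roster1)
        twice = select_normative_trials(once, roster1)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_labels(self, roster1, cohort1):
        sub = select_normative_trials(cohort1, roster1)
        assert set(sub["corroborating_type"].unique()) == {"human", "ai"}


class TestNormativeComparison:
    def test_equal_weights_null_effect(self, roster1):
        params = ParticipantParams(
            beta_bias=0.0, beta_pi=1.2, beta_h=0.8, beta_ai=0.8,
            var_pi=0.3, var_h=0.1, var_ai=0.1, sigma_eps=0.4,
        )
        df = simulate_cohort(60, params, roster1, seed=77)
        table = normative_comparison(select_normative_trials(df, roster1), roster1)
        pooled = table[(table["level"] == "pooled") & (table["outcome"] == "choice")]
        row = pooled.iloc[0]
        assert abs(row["estimate"]) < 2 * row["se"]

    def test_human_preference_detected(self, roster1):
        params = ParticipantParams(
            beta_bias=0.0, beta_pi=1.0, beta_h=0.9, beta_ai=0.6,
            sigma_eps=0.4,
        )
        detections = 0
        for rep in range(5):
            df = simulate_cohort(200, params, roster1, seed=300 + rep)
            table = normative_comparison(
                select_normative_trials(df, roster1), roster1
            )
            row = table[
                (table["level"] == "pooled") & (table["outcome"] == "choice")
            ].iloc[0]
            if row["estimate"] > 0 and row["p"] < 0.05:
                detections += 1
        assert detections >= 3

    def test_separation_flagged_with_finite_fallback(self, roster1):
        # every participant always follows the symptom: perfect prediction
        rows = [
            (f"p{p}", s.id, s.private.direction.value, 90)
            for p in range(6)
            for s in roster1
        ]
        df = pd.DataFrame(
            rows, columns=["participant_id", "scenario_id", "choice", "confidence"]
        )
        table = normative_comparison(select_normative_trials(df, roster1), roster1)
        pooled = table[(table["level"] == "pooled") & (table["outcome"] == "choice")]
        assert pooled.iloc[0]["separation"]
        assert np.isfinite(pooled.iloc[0]["estimate"])

    def test_single_label_rejected(self, roster1, cohort1):
        sub = select_normative_trials(cohort1, roster1)
        with pytest.raises(ValueError):
            normative_comparison(sub[sub["corroborating_type"] == "human"], roster1)


class TestCeilingDiagnostics:
    def test_symmetric_sample_not_saturated(self):
        rng = np.random.default_rng(1)
        diag = ceiling_diagnostics(rng.uniform(0.5, 1.0, 400))
        assert abs(diag.skewness) < 0.3
        assert not diag.saturated

    def test_constructed_ceiling_sample(self):
        # 60% of mass piled at 0.95-1.00 with a long left tail
        rng = np.random.default_rng(2)
        top = rng.uniform(0.95, 1.0, 600)
        tail = rng.uniform(0.5, 0.9, 400) ** 2 * 0.4 / 0.81 + 0.5
        x = np.concatenate([top, tail])
        diag = ceiling_diagnostics(x)
        # verify against independent moment computation
        from scipy import stats

        assert diag.skewness == pytest.approx(stats.skew(x, bias=False))
        assert diag.excess_kurtosis == pytest.approx(
            stats.kurtosis(x, fisher=True, bias=False)
        )
        assert diag.top_decile_share > 0.5
        assert diag.saturated == (
            diag.skewness < -1.8
            and diag.excess_kurtosis > 2.5
            and diag.top_decile_share > 0.5
        )

    def test_constant_vector_degenerate(self):
        diag = ceiling_diagnostics([0.9, 0.9, 0.9, 0.9])
        assert np.isnan(diag.skewness)
        assert not diag.saturated

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ceiling_diagnostics([0.9, 0.8])


class TestMajorityModels:
    def test_accuracy_integrating_cohort_pattern(self, roster2):
        # Bayesian-leaning weights: majority followed when it carries the
        # evidence (HIGH), abandoned when the accurate minority opposes it
        params = ParticipantParams(
            beta_bias=0.0, beta_pi=0.9, beta_h=0.9, beta_ai=0.9, sigma_eps=0.3
        )
        df = simulate_cohort(40, params, roster2, seed=55)
        res = majority_models(df, roster2)
        cells = res.cell_means.set_index(["advisor_type", "accuracy"])
        for t in ("human", "ai"):
            assert cells.loc[(t, "high"), "follow_mean"] > 0.6
            assert cells.loc[(t, "low"), "follow_mean"] < 0.4
        # advisor identity itself should not matter
        type_row = res.choice_model.set_index("term").loc["majority_human"]
        assert abs(type_row["estimate"]) < 3 * type_row["se"]
        low_row = res.choice_model.set_index("term").loc["low_accuracy"]
        assert low_row["estimate"] < 0 and low_row["p"] < 0.01

    def test_blind_majority_follower_ignores_accuracy(self, roster2):
        # participants who always follow the 3-advisor majority: build the
        # cohort directly so the accuracy effect is exactly zero
        rows = []
        maj_dir = {
            s.id: next(iter(s.advisors)).direction.value for s in roster2
        }
        ctx = {s.id: s.context() for s in roster2}
        for p in range(12):
            for s in roster2:
                kinds = [a.kind.value for a in s.advisors]
                majority_kind = max(set(kinds), key=kinds.count)
                d = next(
                    a.direction.value
                    for a in s.advisors
                    if a.kind.value == majority_kind
                )
                rows.append((f"p{p}", s.id, d, 80))
        df = pd.DataFrame(
            rows, columns=["participant_id", "scenario_id", "choice", "confidence"]
        )
        res = majority_models(df, roster2)
        cells = res.cell_means.set_index(["advisor_type", "accuracy"])
        assert (cells["follow_mean"] == 1.0).all()

    def test_cell_means_bounded_and_monotone_in_weights(self, roster2):
        means = []
        for w in (0.3, 1.2):
            params = ParticipantParams(
                beta_bias=0.0, beta_pi=w, beta_h=w, beta_ai=w, sigma_eps=0.3
            )
            df = simulate_cohort(25, params, roster2, seed=66)
            res = majority_models(df, roster2)
            cells = res.cell_means
            assert cells["follow_mean"].between(0, 1).all()
            high = cells[cells["accuracy"] == "high"]["follow_mean"].mean()
            low = cells[cells["accuracy"] == "low"]["follow_mean"].mean()
            means.append(high - low)
        assert means[1] > means[0]  # stronger evidence use -> larger gap

    def test_missing_cells_rejected(self, roster2, cohort2):
        human_maj_ids = {
            s.id
            for s in roster2
            if s.context().majority_kind.value == "human"
        }
        partial = cohort2[cohort2["scenario_id"].isin(human_maj_ids)]
        with pytest.raises(ValueError, match="cells"):
            majority_models(partial, roster2)

    def test_preliminary_anova_detects_accuracy_not_type(self, roster2, cohort2):
        # aggregate-level ANOVA: with equal generative type weights, the
        # accuracy condition dominates and advisor type does not
        table = majority_anova(cohort2, roster2)
        follow = table[table["outcome"] == "follow_maj"].set_index("term")
        assert follow.loc["C(accuracy)", "PR(>F)"] < 0.001
        assert follow.loc["C(advisor_type)", "PR(>F)"] > 0.05

    def test_reference_level_sign_convention(self, roster2):
        # recoding the reference flips the sign of the advisor-type effect
        params = ParticipantParams(
            beta_bias=0.0, beta_pi=0.8, beta_h=1.4, beta_ai=0.5, sigma_eps=0.3
        )
        df = simulate_cohort(30, params, roster2, seed=88)
        res = majority_models(df, roster2)
        est = res.choice_model.set_index("term").loc["majority_human", "estimate"]
        # humans weighted more -> human majorities followed more -> positive
        assert est > 0
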