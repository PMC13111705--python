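"""Scenario design: Bayesian posterior, evidence signals, factorials."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsim.design import (
    AccuracyCondition,
    AdviceSource,
    Corroboration,
    DesignSpec,
    Direction,
    InvalidAccuracyError,
    InvalidSpecError,
    MajorityKind,
    Scenario,
    SourceKind,
    build_design,
    classify_trial,
    evidence_signals,
    flip_directions,
    posterior_prob,
)
from bsim.rosters import (
    STUDY2_CONFIGS,
    read_roster,
    study1_roster,
    study2_roster,
    write_roster,
)

H, AI, PI = SourceKind.HUMAN, SourceKind.AI, SourceKind.PRIVATE
A, S = Direction.A, Direction.S
V = 2.0 / 3.0


def src(kind, direction, acc=V):
    return AdviceSource(kind, direction, acc)


def product_form_posterior(sources, prior_A=0.5):
    """Independent oracle: explicit likelihood-product Bayes rule.

    p(A | signals) = prod_i l_i(A) * prior / (prod_i l_i(A) * prior +
    prod_i l_i(B) * (1 - prior)) with l_i(X) = Acc_i if the signal points
    to X else 1 - Acc_i.
    """
    num_a, num_b = prior_A, 1.0 - prior_A
    for s in sources:
        if s.direction is Direction.A:
            num_a *= s.accuracy
            num_b *= 1.0 - s.accuracy
        else:
            num_a *= 1.0 - s.accuracy
            num_b *= s.accuracy
    return num_a / (num_a + num_b)


FIG1 = [src(AI, A), src(H, S), src(PI, S)]
FIG5 = (
    [AdviceSource(AI, S, 0.65)] * 3
    + [AdviceSource(H, A, 0.55), AdviceSource(PI, A, 0.55)]
)


class TestPosteriorProb:
    def test_equal_validity_worked_example(self):
        # 1 AI->A, 1 human->S, symptom->S, all 2/3 valid: p(S) = 2/3
        assert 1 - posterior_prob(FIG1) == pytest.approx(0.667, abs=5e-4)

    def test_varying_accuracy_worked_example(self):
        # 3 AI->S at 65%, human + symptom ->A at 55%: p(S) = 81%
        assert 1 - posterior_prob(FIG5) == pytest.approx(0.81, abs=5e-3)

    def test_empty_sources_returns_prior(self):
        assert posterior_prob([], prior_A=0.37) == 0.37

    @pytest.mark.parametrize("bad", [0.5, 1.0, 0.3, 1.2])
    def test_invalid_accuracy_rejected(self, bad):
        with pytest.raises(InvalidAccuracyError):
            posterior_prob([AdviceSource(PI, A, bad)])

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([H, AI, PI]),
                st.sampled_from([A, S]),
                st.floats(0.51, 0.99),
            ),
            min_size=0,
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_direction_flip_symmetry(self, spec):
        sources = [AdviceSource(k, d, a) for k, d, a in spec]
        flipped = [AdviceSource(k, d.other, a) for k, d, a in spec]
        assert posterior_prob(sources) + posterior_prob(flipped) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(
        st.lists(
            st.tuples(st.sampled_from([A, S]), st.floats(0.51, 0.99)),
            min_size=0,
            max_size=6,
        ),
        st.floats(0.51, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_agreement_with_product_form_oracle(self, spec, acc):
        sources = [AdviceSource(H, d, a) for d, a in spec]
        assert posterior_prob(sources) == pytest.approx(
            product_form_posterior(sources), abs=1e-12
        )

    @given(
        st.lists(
            st.tuples(st.sampled_from([A, S]), st.floats(0.51, 0.99)),
            min_size=1,
            max_size=5,
        ),
        st.floats(0.51, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_appending_A_signal_increases_posterior(self, spec, acc):
        sources = [AdviceSource(H, d, a) for d, a in spec]
        extended = sources + [AdviceSource(AI, A, acc)]
        assert posterior_prob(extended) > posterior_prob(sources)

    def test_equal_validity_closed_form(self):
        # with common validity v the posterior depends only on the net count
        for delta in range(-4, 5):
            n_a = max(delta, 0) + 2
            n_b = n_a - delta
            sources = [src(H, A)] * n_a + [src(AI, S)] * n_b
            closed = 1.0 / (1.0 + ((1 - V) / V) ** delta)
            assert posterior_prob(sources) == pytest.approx(closed, abs=1e-12)


class TestEvidenceSignals:
    def test_equal_validity_components(self):
        sources = [src(H, A), src(H, A), src(AI, S), src(PI, A)]
        sig = evidence_signals(sources)
        ln2 = math.log(2.0)
        assert sig.x_pi == pytest.approx(ln2, abs=1e-12)
        assert sig.x_h == pytest.approx(2 * ln2, abs=1e-12)
        assert sig.x_ai == pytest.approx(-ln2, abs=1e-12)

    def test_varying_accuracy_components(self):
        sig = evidence_signals(FIG5)
        lr55 = math.log(55 / 45)
        lr65 = math.log(65 / 35)
        assert sig.x_pi == pytest.approx(lr55, abs=1e-9)
        assert sig.x_h == pytest.approx(lr55, abs=1e-9)
        assert sig.x_ai == pytest.approx(-3 * lr65, abs=1e-9)

    def test_private_only(self):
        sig = evidence_signals([src(PI, A)])
        assert (sig.x_pi, sig.x_h, sig.x_ai) == pytest.approx(
            (math.log(2.0), 0.0, 0.0)
        )

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([H, AI, PI]),
                st.sampled_from([A, S]),
                st.floats(0.51, 0.99),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_components_sum_to_logit_posterior(self, spec):
        # additivity: the three per-type sums carry exactly the total
        # evidence (checked on the numerically stable probability scale)
        sources = [AdviceSource(k, d, a) for k, d, a in spec]
        p = posterior_prob(sources)
        total = evidence_signals(sources).total()
        assert 1.0 / (1.0 + math.exp(-total)) == pytest.approx(p, abs=1e-12)


class TestBuildDesign:
    def test_equal_validity_factorial_levels(self):
        scenarios = build_design(DesignSpec(study=1))
        levels = sorted({s.posterior_level for s in scenarios})
        assert levels == [0.5, 0.67, 0.80, 0.89]

    def test_equal_validity_roster_size(self):
        assert len(study1_roster()) == 52

    def test_net_evidence_three_gives_eight_ninths(self):
        sources = [src(H, A), src(AI, A), src(PI, A)]
        scen = Scenario("x", 1, tuple(sources))
        assert scen.net_evidence == 3
        assert scen.posterior_A == pytest.approx(8 / 9, abs=1e-12)
        assert scen.posterior_level == 0.89

    def test_varying_accuracy_roster(self):
        roster = study2_roster()
        assert len(roster) == 72
        levels = sorted({s.posterior_level for s in roster})
        assert levels == [0.56, 0.65, 0.75, 0.81, 0.89, 0.99]

    def test_custom_exclusion_predicate(self):
        everything = build_design(DesignSpec(study=1, exclude=lambda adv: False))
        assert len(everything) == 68  # full factorial before exclusion

    def test_inconsistent_majority_sizes_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_design(
                DesignSpec(
                    study=2,
                    study2_configs=STUDY2_CONFIGS,
                    majority_size=1,
                    minority_size=1,
                )
            )

    def test_roster_csv_roundtrip(self, tmp_path, roster1):
        path = tmp_path / "roster.csv"
        write_roster(roster1, path)
        back = read_roster(path)
        assert [s.id for s in back] == [s.id for s in roster1]
        for a, b in zip(back, roster1):
            assert a.posterior_A == pytest.approx(b.posterior_A, abs=1e-9)

    def test_packaged_fixture_matches_generator(self, roster1, roster2):
        for packaged, generated in ((roster1, study1_roster()), (roster2, study2_roster())):
            assert len(packaged) == len(generated)
            for a, b in zip(packaged, generated):
                assert a.id == b.id
                assert sorted(
                    (s.kind, s.direction, round(s.accuracy, 6)) for s in a.sources
                ) == sorted(
                    (s.kind, s.direction, round(s.accuracy, 6)) for s in b.sources
                )


class TestClassifyTrial:
    def test_majority_with_superior_accuracy(self):
        ctx = classify_trial(Scenario("x", 2, tuple(FIG5)))
        assert ctx.majority_kind is MajorityKind.AI
        assert ctx.majority_accuracy_condition is AccuracyCondition.HIGH

    def test_balanced_team_human_corroborates(self):
        scen = Scenario("x", 1, (src(H, A), src(AI, S), src(PI, A)))
        ctx = classify_trial(scen)
        assert ctx.corroboration is Corroboration.HUMAN_CORROBORATES_PI
        assert ctx.majority_kind is MajorityKind.NONE

    def test_all_advisors_contradict(self):
        scen = Scenario("x", 1, (src(H, S), src(AI, S), src(PI, A)))
        assert classify_trial(scen).corroboration is Corroboration.ALL_CONTRADICT

    def test_both_types_agree_with_pi(self):
        scen = Scenario("x", 1, (src(H, A), src(AI, A), src(PI, A)))
        assert classify_trial(scen).corroboration is Corroboration.BOTH_SAME

    def test_pure_team_corroborates(self):
        scen = Scenario("x", 1, (src(AI, A), src(AI, A), src(PI, A)))
        assert classify_trial(scen).corroboration is Corroboration.AI_CORROBORATES_PI


def test_flip_directions_involution(roster1):
    for scen in roster1[:10]:
        twice = flip_directions(flip_directions(scen))
        assert [s.direction for s in twice.sources] == [
            s.direction for s in scen.sources
        ]
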