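"""Information-cascade scenario design and the Bayesian benchmark.

A scenario in the cascade paradigm bundles one piece of *private*
information (the patient's symptom, seen only by the decision maker) with
one to three pieces of *public* information (prior diagnoses from human or
AI advisors).  Every signal points towards one of two diseases —
``A`` (appendicitis) or ``S`` (sigmoid diverticulitis) — and carries a
validity ``Acc``: the probability that the signal points to the true
disease.  A rational decision maker combines the signals by Bayesian
updating; on the log-odds scale each signal simply contributes its signed
log-likelihood ratio ``± ln(Acc / (1 - Acc))``.

This module provides the scenario containers, the Bayesian posterior
benchmark, the per-source-type evidence signals used as predictors in the
social influence model, the factorial design generator, and the trial
classification (corroboration / majority structure) used by the normative
analyses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

__all__ = [
    "Direction",
    "SourceKind",
    "Corroboration",
    "MajorityKind",
    "AccuracyCondition",
    "AdviceSource",
    "Scenario",
    "TrialContext",
    "DesignSpec",
    "InvalidAccuracyError",
    "InvalidSpecError",
    "EvidenceSignals",
    "log_likelihood_ratio",
    "posterior_prob",
    "evidence_signals",
    "build_design",
    "classify_trial",
    "flip_directions",
]


class Direction(str, Enum):
    """Which disease a signal points to."""

    A = "A"  # appendicitis
    S = "S"  # sigmoid diverticulitis

    @property
    def other(self) -> "Direction":
        return Direction.S if self is Direction.A else Direction.A


class SourceKind(str, Enum):
    HUMAN = "human"
    AI = "ai"
    PRIVATE = "private"


class Corroboration(str, Enum):
    """Who, if anyone, corroborates the private information."""

    HUMAN_CORROBORATES_PI = "human_corroborates_pi"
    AI_CORROBORATES_PI = "ai_corroborates_pi"
    BOTH_SAME = "both_same"
    ALL_CONTRADICT = "all_contradict"
    OTHER = "other"


class MajorityKind(str, Enum):
    HUMAN = "human"
    AI = "ai"
    NONE = "none"


class AccuracyCondition(str, Enum):
    HIGH = "high"
    LOW = "low"
    NONE = "none"


class MostLikely(str, Enum):
    A = "A"
    S = "S"
    TIE = "tie"


class InvalidAccuracyError(ValueError):
    """Signal validity must lie strictly between 0.5 and 1."""


class InvalidSpecError(ValueError):
    """The design specification is internally inconsistent."""


def _check_accuracy(accuracy: float) -> None:
    if not (0.5 < accuracy < 1.0):
        raise InvalidAccuracyError(
            f"accuracy must lie strictly in (0.5, 1.0); got {accuracy!r}"
        )


@dataclass(frozen=True)
class AdviceSource:
    """One signal: the private symptom or one advisor's diagnosis.

    ``accuracy`` is the validity p(signal points to X | disease is X),
    constrained to (0.5, 1): a signal at 0.5 carries no information and one
    at 1.0 would be definitive, neither of which occurs in the paradigm.
    """

    kind: SourceKind
    direction: Direction
    accuracy: float

    def __post_init__(self) -> None:
        _check_accuracy(self.accuracy)

    @property
    def sign(self) -> int:
        """+1 if the signal points to A, -1 if it points to S."""
        return 1 if self.direction is Direction.A else -1


def log_likelihood_ratio(source: AdviceSource) -> float:
    """Signed log-likelihood ratio of the signal on the A-positive scale."""
    return source.sign * math.log(source.accuracy / (1.0 - source.accuracy))


def posterior_prob(
    sources: Sequence[AdviceSource], prior_A: float = 0.5
) -> float:
    """Posterior probability of disease A given all signals.

    Bayesian updating with conditionally independent signals reduces, on
    the log-odds scale, to adding each signal's signed log-likelihood
    ratio to the prior log-odds:

        logit p(A | signals) = logit(prior_A) + sum_i d_i ln(Acc_i / (1-Acc_i))

    with d_i = +1 for a signal pointing to A and -1 for S.  An empty signal
    list returns the prior unchanged.
    """
    if not (0.0 < prior_A < 1.0):
        raise ValueError(f"prior_A must lie in (0, 1); got {prior_A!r}")
    for s in sources:
        _check_accuracy(s.accuracy)
    logodds = math.log(prior_A / (1.0 - prior_A))
    logodds += sum(log_likelihood_ratio(s) for s in sources)
    return 1.0 / (1.0 + math.exp(-logodds))


@dataclass(frozen=True)
class EvidenceSignals:
    """Per-source-type summed signed log-likelihood ratios (A-positive)."""

    x_pi: float
    x_h: float
    x_ai: float

    def total(self) -> float:
        return self.x_pi + self.x_h + self.x_ai

    def __iter__(self):
        return iter((self.x_pi, self.x_h, self.x_ai))


_KIND_TO_FIELD = {
    SourceKind.PRIVATE: "x_pi",
    SourceKind.HUMAN: "x_h",
    SourceKind.AI: "x_ai",
}


def evidence_signals(sources: Sequence[AdviceSource]) -> EvidenceSignals:
    """Split the total Bayesian evidence into PI / human / AI components.

    Each component is the sum, over signals of that kind, of the signed
    log-likelihood ratio ``d_i ln(Acc_i/(1-Acc_i))``.  At a uniform prior
    the three components sum to ``logit(posterior_prob(sources))``.
    """
    acc = {"x_pi": 0.0, "x_h": 0.0, "x_ai": 0.0}
    for s in sources:
        _check_accuracy(s.accuracy)
        acc[_KIND_TO_FIELD[s.kind]] += log_likelihood_ratio(s)
    return EvidenceSignals(**acc)


@dataclass(frozen=True)
class TrialContext:
    """Composition labels used by the normative and majority analyses."""

    corroboration: Corroboration
    majority_kind: MajorityKind
    majority_accuracy_condition: AccuracyCondition


def _round_half_up(x: float, ndigits: int) -> float:
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class Scenario:
    """One decision scenario: 1 private signal + 1..3 advisor signals."""

    id: str
    study: int  # 1 = equal validity, 2 = varying accuracy
    sources: tuple[AdviceSource, ...]

    def __post_init__(self) -> None:
        n_private = sum(1 for s in self.sources if s.kind is SourceKind.PRIVATE)
        if n_private != 1:
            raise InvalidSpecError(
                f"scenario {self.id!r} must contain exactly one private "
                f"source; got {n_private}"
            )

    @property
    def private(self) -> AdviceSource:
        return next(s for s in self.sources if s.kind is SourceKind.PRIVATE)

    @property
    def advisors(self) -> tuple[AdviceSource, ...]:
        return tuple(s for s in self.sources if s.kind is not SourceKind.PRIVATE)

    @property
    def posterior_A(self) -> float:
        return posterior_prob(self.sources)

    @property
    def posterior_favored(self) -> float:
        """Posterior of the more likely disease (>= 0.5)."""
        p = self.posterior_A
        return max(p, 1.0 - p)

    @property
    def posterior_level(self) -> float:
        """Favored-disease posterior rounded half-up to 2 dp.

        Matches the printed design levels (e.g. 2/3 -> 0.67, 8/9 -> 0.89).
        """
        return _round_half_up(self.posterior_favored, 2)

    @property
    def most_likely(self) -> MostLikely:
        p = self.posterior_A
        if math.isclose(p, 0.5, abs_tol=1e-12):
            return MostLikely.TIE
        return MostLikely.A if p > 0.5 else MostLikely.S

    @property
    def net_evidence(self) -> int | None:
        """n_a - n_b over all signals; defined for equal-validity scenarios."""
        accs = {s.accuracy for s in self.sources}
        if len(accs) != 1:
            return None
        return sum(s.sign for s in self.sources)

    def signals(self) -> EvidenceSignals:
        return evidence_signals(self.sources)

    def context(self) -> TrialContext:
        return classify_trial(self)


def flip_directions(scenario: Scenario, new_id: str | None = None) -> Scenario:
    """Mirror scenario: every signal points to the other disease."""
    flipped = tuple(
        AdviceSource(s.kind, s.direction.other, s.accuracy)
        for s in scenario.sources
    )
    return Scenario(
        id=new_id if new_id is not None else scenario.id + "-flipped",
        study=scenario.study,
        sources=flipped,
    )


def classify_trial(scenario: Scenario) -> TrialContext:
    """Assign corroboration, majority kind and HIGH/LOW accuracy condition.

    Corroboration follows the trial-selection logic of the normative
    analysis: a type "corroborates" the private information when all its
    advisors point the same way as the symptom.  Mixed teams in which
    humans and AI give the same diagnosis, and teams whose advice
    uniformly contradicts the symptom, are labelled for exclusion; teams
    with within-type disagreement fall into OTHER.
    """
    advisors = scenario.advisors
    if not advisors:
        raise InvalidSpecError("classify_trial requires at least one advisor")
    pi_dir = scenario.private.direction

    humans = [s for s in advisors if s.kind is SourceKind.HUMAN]
    ais = [s for s in advisors if s.kind is SourceKind.AI]

    def unanimous(group: list[AdviceSource]) -> Direction | None:
        dirs = {s.direction for s in group}
        return next(iter(dirs)) if len(dirs) == 1 else None

    h_dir = unanimous(humans) if humans else None
    ai_dir = unanimous(ais) if ais else None

    if humans and ais:
        if h_dir is None or ai_dir is None:
            corrob = Corroboration.OTHER
        elif h_dir == ai_dir:
            corrob = (
                Corroboration.BOTH_SAME
                if h_dir == pi_dir
                else Corroboration.ALL_CONTRADICT
            )
        elif h_dir == pi_dir:
            corrob = Corroboration.HUMAN_CORROBORATES_PI
        else:
            corrob = Corroboration.AI_CORROBORATES_PI
    else:
        group_dir, kind = (h_dir, SourceKind.HUMAN) if humans else (ai_dir, SourceKind.AI)
        if group_dir is None:
            corrob = Corroboration.OTHER
        elif group_dir == pi_dir:
            corrob = (
                Corroboration.HUMAN_CORROBORATES_PI
                if kind is SourceKind.HUMAN
                else Corroboration.AI_CORROBORATES_PI
            )
        else:
            corrob = Corroboration.ALL_CONTRADICT

    n_h, n_ai = len(humans), len(ais)
    if n_h > n_ai:
        majority = MajorityKind.HUMAN
    elif n_ai > n_h:
        majority = MajorityKind.AI
    else:
        majority = MajorityKind.NONE

    condition = AccuracyCondition.NONE
    if majority is not MajorityKind.NONE and humans and ais:
        maj_acc = humans[0].accuracy if majority is MajorityKind.HUMAN else ais[0].accuracy
        min_acc = ais[0].accuracy if majority is MajorityKind.HUMAN else humans[0].accuracy
        if maj_acc > min_acc:
            condition = AccuracyCondition.HIGH
        elif maj_acc < min_acc:
            condition = AccuracyCondition.LOW

    return TrialContext(corrob, majority, condition)


# ---------------------------------------------------------------------------
# Factorial design generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study2Config:
    """One accuracy geometry for a 3-vs-1 varying-accuracy scenario.

    The three majority advisors share ``majority_accuracy`` and point one
    way; the single minority advisor (``minority_accuracy``) opposes them;
    the private symptom (``pi_accuracy``) sides with the majority when
    ``pi_with_majority`` else with the minority.
    """

    majority_accuracy: float
    minority_accuracy: float
    pi_accuracy: float
    pi_with_majority: bool = False


def exclude_unanimous_triples(advisors: tuple[tuple[SourceKind, Direction], ...]) -> bool:
    """Default equal-validity exclusion: drop 3-advisor unanimous teams.

    Three advisors all pointing the same way would push the favored
    posterior to 0.94 (net evidence 4), a level outside the four-level
    design; dropping them leaves 52 scenarios at levels
    {0.5, 0.67, 0.80, 0.89}.
    """
    return len(advisors) == 3 and len({d for _, d in advisors}) == 1


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial scenario design.

    Study 1 (equal validity): every signal carries ``validity``; teams of
    ``advisor_counts`` advisors over all (type, direction) multisets are
    crossed with the private-signal direction, then filtered by
    ``exclude`` (default: :func:`exclude_unanimous_triples`).

    Study 2 (varying accuracy): each entry of ``study2_configs`` is
    crossed with the majority type and the majority direction.
    """

    study: int = 1
    validity: float = 2.0 / 3.0
    advisor_counts: tuple[int, ...] = (1, 2, 3)
    exclude: Callable[[tuple[tuple[SourceKind, Direction], ...]], bool] | None = None
    study2_configs: tuple[Study2Config, ...] = ()
    majority_size: int = 3
    minority_size: int = 1
    id_prefix: str | None = None


def _study1_scenarios(spec: DesignSpec) -> list[Scenario]:
    _check_accuracy(spec.validity)
    if any(n < 1 for n in spec.advisor_counts):
        raise InvalidSpecError("advisor counts must be >= 1")
    exclude = spec.exclude if spec.exclude is not None else exclude_unanimous_triples
    prefix = spec.id_prefix or "S1"
    scenarios: list[Scenario] = []
    idx = 0
    kinds = (SourceKind.HUMAN, SourceKind.AI)
    dirs = (Direction.A, Direction.S)
    for n in spec.advisor_counts:
        # multiset semantics: advisors of the same (type, direction) are
        # interchangeable, so enumerate sorted combinations with replacement
        combos = sorted(
            {
                tuple(sorted(c, key=lambda td: (td[0].value, td[1].value)))
                for c in itertools.combinations_with_replacement(
                    itertools.product(kinds, dirs), n
                )
            }
        )
        for advisors in combos:
            if exclude(advisors):
                continue
            for pi_dir in dirs:
                idx += 1
                sources = tuple(
                    AdviceSource(kind, direction, spec.validity)
                    for kind, direction in advisors
                ) + (AdviceSource(SourceKind.PRIVATE, pi_dir, spec.validity),)
                scenarios.append(
                    Scenario(id=f"{prefix}-{idx:03d}", study=1, sources=sources)
                )
    return scenarios


def _study2_scenarios(spec: DesignSpec) -> list[Scenario]:
    if not spec.study2_configs:
        raise InvalidSpecError("study 2 design requires study2_configs")
    if spec.majority_size <= spec.minority_size:
        raise InvalidSpecError(
            f"majority size ({spec.majority_size}) must exceed minority size "
            f"({spec.minority_size})"
        )
    prefix = spec.id_prefix or "S2"
    scenarios: list[Scenario] = []
    idx = 0
    for cfg in spec.study2_configs:
        for maj_kind in (SourceKind.HUMAN, SourceKind.AI):
            min_kind = SourceKind.AI if maj_kind is SourceKind.HUMAN else SourceKind.HUMAN
            for maj_dir in (Direction.A, Direction.S):
                min_dir = maj_dir.other
                pi_dir = maj_dir if cfg.pi_with_majority else min_dir
                idx += 1
                sources = (
                    tuple(
                        AdviceSource(maj_kind, maj_dir, cfg.majority_accuracy)
                        for _ in range(spec.majority_size)
                    )
                    + tuple(
                        AdviceSource(min_kind, min_dir, cfg.minority_accuracy)
                        for _ in range(spec.minority_size)
                    )
                    + (AdviceSource(SourceKind.PRIVATE, pi_dir, cfg.pi_accuracy),)
                )
                scenarios.append(
                    Scenario(id=f"{prefix}-{idx:03d}", study=2, sources=sources)
                )
    return scenarios


def build_design(spec: DesignSpec) -> list[Scenario]:
    """Generate the full factorial scenario roster for a design spec."""
    if spec.study == 1:
        return _study1_scenarios(spec)
    if spec.study == 2:
        return _study2_scenarios(spec)
    raise InvalidSpecError(f"unknown study profile {spec.study!r}")
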