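"""Generative Bayesian Social Influence Model: synthetic cohorts.

Each simulated participant carries realised weights for the four terms of
the social influence model — a bias toward disease A and one weight per
signal type (private information, human advice, AI advice).  Weights are
drawn around cohort-level fixed effects with independent normal
between-participant heterogeneity.  On each trial the participant forms a
noisy perceived log-odds

    eta = bias + b_PI * x_PI + b_H * x_H + b_AI * x_AI + eps,
    eps ~ N(0, sigma_eps^2),

chooses the disease favored by ``expit(eta)`` and reports confidence as
the perceived probability of the chosen disease, rounded to integer
percent on the 50–100 response scale.  A weight of 1 on every signal with
zero bias and zero noise reproduces the ideal Bayesian observer.

Cohort tables stand in for the deposited behavioural data: 60
participants × 52 scenarios (equal-validity profile) or 50 × 72
(varying-accuracy profile), each participant answering every roster
scenario in randomised order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import Direction, Scenario

__all__ = [
    "ParticipantParams",
    "RealisedWeights",
    "TrialResponse",
    "STUDY1_PARAMS",
    "STUDY2_PARAMS",
    "draw_participant",
    "simulate_response",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Cohort-level parameters of the generative social influence model.

    ``beta_*`` are fixed effects (log-odds scale), ``var_*`` the
    between-participant variances of the corresponding weights, and
    ``sigma_eps`` the trial-level noise SD on the log-odds scale.
    """

    beta_bias: float
    beta_pi: float
    beta_h: float
    beta_ai: float
    var_bias: float = 0.0
    var_pi: float = 0.0
    var_h: float = 0.0
    var_ai: float = 0.0
    sigma_eps: float = 0.24

    def __post_init__(self) -> None:
        for name in ("var_bias", "var_pi", "var_h", "var_ai"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")


# Published cohort-level estimates used as generative defaults.  The
# residual SDs borrow the reported informational-influence model values
# (0.24 / 0.25); the weight-model residual SD itself is not reported.
STUDY1_PARAMS = ParticipantParams(
    beta_bias=0.14, beta_pi=1.41, beta_h=1.00, beta_ai=0.87,
    var_bias=0.09, var_pi=1.95, var_h=0.71, var_ai=0.53,
    sigma_eps=0.24,
)
STUDY2_PARAMS = ParticipantParams(
    beta_bias=0.20, beta_pi=0.72, beta_h=0.302, beta_ai=0.30,
    var_bias=0.33, var_pi=1.55, var_h=0.11, var_ai=0.10,
    sigma_eps=0.25,
)


@dataclass(frozen=True)
class RealisedWeights:
    bias: float
    pi: float
    h: float
    ai: float


@dataclass(frozen=True)
class TrialResponse:
    participant_id: str
    scenario_id: str
    choice: Direction
    confidence: int  # integer percent in [50, 100]

    def __post_init__(self) -> None:
        if not (50 <= self.confidence <= 100):
            raise ValueError(f"confidence must be in [50, 100]; got {self.confidence}")


def draw_participant(
    params: ParticipantParams, rng: np.random.Generator
) -> RealisedWeights:
    """Realise one participant's weights: fixed effect + N(0, var) draw.

    The random-effects covariance is diagonal — the studies report only
    variances, never covariances.
    """
    sds = np.sqrt([params.var_bias, params.var_pi, params.var_h, params.var_ai])
    noise = rng.standard_normal(4) * sds
    return RealisedWeights(
        bias=params.beta_bias + noise[0],
        pi=params.beta_pi + noise[1],
        h=params.beta_h + noise[2],
        ai=params.beta_ai + noise[3],
    )


def simulate_response(
    weights: RealisedWeights,
    scenario: Scenario,
    sigma_eps: float,
    rng: np.random.Generator,
    participant_id: str = "p0",
    probability_matching: bool = False,
) -> TrialResponse:
    """Simulate one choice + confidence rating for a scenario.

    The default choice rule is the deterministic argmax of the noisy
    perceived posterior (all stochasticity lives in the log-odds noise).
    ``probability_matching`` instead samples the choice with the perceived
    probability, leaving the confidence readout unchanged.
    """
    x = scenario.signals()
    eta = (
        weights.bias
        + weights.pi * x.x_pi
        + weights.h * x.x_h
        + weights.ai * x.x_ai
        + rng.normal(0.0, sigma_eps)
    )
    p_a = 1.0 / (1.0 + np.exp(-eta))
    if probability_matching:
        choice = Direction.A if rng.random() < p_a else Direction.S
    elif p_a > 0.5:
        choice = Direction.A
    elif p_a < 0.5:
        choice = Direction.S
    else:  # exact tie: fair coin
        choice = Direction.A if rng.random() < 0.5 else Direction.S
    p_choice = p_a if choice is Direction.A else 1.0 - p_a
    confidence = int(np.clip(round(100.0 * max(p_choice, 1.0 - p_choice)), 50, 100))
    return TrialResponse(participant_id, scenario.id, choice, confidence)


def simulate_cohort(
    n_participants: int,
    params: ParticipantParams,
    roster: Sequence[Scenario],
    seed: int,
    probability_matching: bool = False,
) -> pd.DataFrame:
    """Simulate a full cohort: every participant answers every scenario.

    Scenario order is randomised independently per participant.  Returns a
    long-format table (participant_id, scenario_id, trial_index, choice,
    confidence) whose ``attrs`` carry the generating seed and parameters;
    the table is exactly reproducible from (params, roster, seed).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if not roster:
        raise ValueError("roster must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    width = len(str(n_participants))
    for i in range(n_participants):
        pid = f"p{i + 1:0{width}d}"
        weights = draw_participant(params, rng)
        order = rng.permutation(len(roster))
        for t, j in enumerate(order):
            resp = simulate_response(
                weights, roster[j], params.sigma_eps, rng,
                participant_id=pid, probability_matching=probability_matching,
            )
            rows.append(
                (pid, resp.scenario_id, t, resp.choice.value, resp.confidence)
            )
    df = pd.DataFrame(
        rows, columns=["participant_id", "scenario_id", "trial_index", "choice", "confidence"]
    )
    from .rosters import roster_hash

    df.attrs["metadata"] = {
        "seed": seed,
        "n_participants": n_participants,
        "params": asdict(params),
        "roster_hash": roster_hash(roster),
        "probability_matching": probability_matching,
    }
    return df


def cohort_metadata_json(df: pd.DataFrame) -> str:
    """Serialise the cohort's generating metadata (sidecar JSON)."""
    return json.dumps(df.attrs.get("metadata", {}), indent=2, sort_keys=True)
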