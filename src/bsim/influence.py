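"""Estimating the social influence weights from trial data.

The social influence model regresses the participant's *perceived*
posterior log-odds of disease A — read off the reported choice confidence
— on the three per-source-type evidence signals:

    ln p_perceived(A)/p_perceived(S)
        = b_bias + b_PI x_PI + b_H x_H + b_AI x_AI

with a per-participant random intercept and independent random slopes.
A weight of 1 is the normatively correct Bayesian use of a signal; above
1 means over-weighting, below 1 conservative integration.  On
equal-validity data each x is an integer multiple of ln 2, so the
count-based and accuracy-weighted formulations coincide exactly.

Estimation is a linear mixed model (statsmodels MixedLM); weight
comparisons are Wald contrasts on the fixed-effect covariance.  The
companion informational-influence model regresses logit-transformed
confidence in the most likely diagnosis on its posterior probability,
optionally interacted with the advisor-type mix; its residual SD feeds
the equivalence (TOST) procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .design import Direction, MostLikely, Scenario, SourceKind

__all__ = [
    "FixedEffect",
    "REVariance",
    "FitResult",
    "ContrastResult",
    "InvalidConfidenceError",
    "ScenarioJoinError",
    "confidence_for_option",
    "perceived_logodds",
    "build_model_matrix",
    "fit_social_influence",
    "contrast_weights",
    "fit_confidence_vs_posterior",
]


class InvalidConfidenceError(ValueError):
    """Confidence ratings live on the 50-100 percent scale."""


class ScenarioJoinError(KeyError):
    """Trial rows referenced scenario ids absent from the roster."""

    def __init__(self, offenders: Sequence[str]):
        self.offenders = sorted(set(offenders))
        super().__init__(
            f"{len(self.offenders)} scenario id(s) not in roster: "
            f"{self.offenders[:10]}"
        )


def confidence_for_option(
    choice: Direction | str, confidence: float, target_option: Direction | str
) -> float:
    """Recode confidence-in-chosen-option to confidence in ``target_option``.

    A rating of 60% for the chosen disease implies 100 - 60 = 40% for the
    other one.  Input confidence must lie on the response scale [50, 100];
    the result spans [0, 100] (clipping, if any, happens downstream).
    """
    if not (50 <= confidence <= 100):
        raise InvalidConfidenceError(
            f"confidence must be in [50, 100]; got {confidence!r}"
        )
    if Direction(choice) == Direction(target_option):
        return float(confidence)
    return 100.0 - float(confidence)


def perceived_logodds(
    choice: Direction | str, confidence: float, clip: float = 0.005
) -> float:
    """Perceived log-odds of disease A implied by a choice + confidence.

    The implied p(A) is clamped into [clip, 1 - clip] before the logit so
    that 100%-confident responses (common on the integer scale) stay
    finite.  A confidence of exactly 50% maps to log-odds 0 regardless of
    the recorded choice.
    """
    if not (0.0 < clip < 0.5):
        raise ValueError(f"clip must lie in (0, 0.5); got {clip!r}")
    p_a = confidence_for_option(choice, confidence, Direction.A) / 100.0
    p_a = min(max(p_a, clip), 1.0 - clip)
    return math.log(p_a / (1.0 - p_a))


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    stat: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class REVariance:
    estimate: float
    se: float | None
    p: float | None


@dataclass
class FitResult:
    """A fitted mixed model: estimates, uncertainty, and diagnostics."""

    fixed_effects: dict[str, FixedEffect]
    re_variances: dict[str, REVariance]
    residual_sd: float
    fixed_cov: pd.DataFrame
    n_participants: int
    n_trials: int
    converged: bool
    loglik: float
    method: str  # "reml" or "ml"
    inference: str  # "z" or "t"

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"term": k, "estimate": v.estimate, "se": v.se, "stat": v.stat,
             "p": v.p, "ci_low": v.ci_low, "ci_high": v.ci_high}
            for k, v in self.fixed_effects.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple[str, str]
    beta_diff: float
    z: float
    p: float


def _signal_frame(roster: Sequence[Scenario]) -> Mapping[str, tuple]:
    return {s.id: s.signals() for s in roster}


def build_model_matrix(
    trials: pd.DataFrame, roster: Sequence[Scenario], clip: float = 0.005
) -> pd.DataFrame:
    """Join trials to their scenarios and construct the regression rows.

    Returns one row per trial with the perceived log-odds response ``y``
    and the three evidence-signal predictors.  Raises
    :class:`ScenarioJoinError` listing every unresolvable scenario id.
    """
    signals = _signal_frame(roster)
    missing = [sid for sid in trials["scenario_id"].unique() if sid not in signals]
    if missing:
        raise ScenarioJoinError(missing)
    sig = trials["scenario_id"].map(signals)
    out = pd.DataFrame(
        {
            "participant_id": trials["participant_id"].to_numpy(),
            "scenario_id": trials["scenario_id"].to_numpy(),
            "y": [
                perceived_logodds(c, conf, clip)
                for c, conf in zip(trials["choice"], trials["confidence"])
            ],
            "x_pi": [v.x_pi for v in sig],
            "x_h": [v.x_h for v in sig],
            "x_ai": [v.x_ai for v in sig],
        }
    )
    return out


_FE_NAME_MAP = {"Intercept": "bias", "x_pi": "pi", "x_h": "h", "x_ai": "ai"}


def _extract_fit(
    result,
    fe_name_map: Mapping[str, str],
    re_name_map: Mapping[str, str],
    n_participants: int,
    n_trials: int,
    method: str,
    inference: str,
) -> FitResult:
    fe_params = result.fe_params
    k = len(fe_params)
    cov = result.cov_params().iloc[:k, :k]
    if inference == "t":
        df_resid = max(n_participants - 1, 1)
        crit = stats.t.ppf(0.975, df_resid)
        pfun = lambda z: 2 * stats.t.sf(abs(z), df_resid)
    else:
        crit = stats.norm.ppf(0.975)
        pfun = lambda z: 2 * stats.norm.sf(abs(z))
    fixed: dict[str, FixedEffect] = {}
    names: list[str] = []
    for raw in fe_params.index:
        name = fe_name_map.get(raw, raw)
        names.append(name)
        est = float(fe_params[raw])
        se = float(np.sqrt(cov.loc[raw, raw]))
        z = est / se if se > 0 else float("nan")
        fixed[name] = FixedEffect(
            estimate=est, se=se, stat=z, p=float(pfun(z)),
            ci_low=est - crit * se, ci_high=est + crit * se,
        )
    fixed_cov = cov.copy()
    fixed_cov.index = names
    fixed_cov.columns = names

    re_vars: dict[str, REVariance] = {}
    # random intercept variance
    intercept_var = float(result.cov_re.iloc[0, 0]) if result.k_re else None
    # variance components (independent random slopes), in model order
    vc_names = list(result.model.exog_vc.names) if result.k_vc else []
    # variance-parameter SEs are reported on the residual-variance-profiled
    # scale; multiply by the residual variance to express them as variances
    bse = result.bse
    scale = float(result.scale)
    if intercept_var is not None:
        raw = "Group Var"
        se = float(bse[raw]) * scale if raw in bse.index else None
        re_vars[re_name_map.get("intercept", "intercept")] = _re_variance(
            intercept_var, se
        )
    for i, vc in enumerate(vc_names):
        raw = f"{vc} Var"
        se = float(bse[raw]) * scale if raw in bse.index else None
        re_vars[re_name_map.get(vc, vc)] = _re_variance(float(result.vcomp[i]), se)

    return FitResult(
        fixed_effects=fixed,
        re_variances=re_vars,
        residual_sd=float(np.sqrt(result.scale)),
        fixed_cov=fixed_cov,
        n_participants=n_participants,
        n_trials=n_trials,
        converged=bool(result.converged),
        loglik=float(result.llf),
        method=method,
        inference=inference,
    )


def _re_variance(est: float, se: float | None) -> REVariance:
    # one-sided Wald test of variance > 0; crude but matches common reporting
    if se is None or not np.isfinite(se) or se <= 0:
        return REVariance(est, None, None)
    return REVariance(est, se, float(stats.norm.sf(est / se)))


def fit_social_influence(
    model_matrix: pd.DataFrame,
    reml: bool = True,
    inference: str = "z",
) -> FitResult:
    """Fit the social influence model by linear mixed-effects regression.

    Response and predictors come from :func:`build_model_matrix`; the
    random-effects structure is a per-participant intercept plus
    independent (diagonal-covariance) random slopes on the three signals.
    Non-convergence is flagged on the result, not raised; a variance
    component estimated at the zero boundary stays at 0 with a warning
    from the optimiser.
    """
    participants = model_matrix["participant_id"].unique()
    if len(participants) < 2:
        raise ValueError("random effects are unidentifiable with < 2 participants")
    counts = model_matrix.groupby("participant_id").size()
    if (counts < 2).any():
        raise ValueError("every participant needs >= 2 trials")
    model = smf.mixedlm(
        "y ~ x_pi + x_h + x_ai",
        model_matrix,
        groups=model_matrix["participant_id"],
        re_formula="1",
        vc_formula={"x_pi": "0 + x_pi", "x_h": "0 + x_h", "x_ai": "0 + x_ai"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    return _extract_fit(
        result,
        _FE_NAME_MAP,
        {"intercept": "bias", "x_pi": "pi", "x_h": "h", "x_ai": "ai"},
        n_participants=len(participants),
        n_trials=len(model_matrix),
        method="reml" if reml else "ml",
        inference=inference,
    )


def contrast_weights(fit: FitResult, name_a: str, name_b: str) -> ContrastResult:
    """Wald contrast between two fixed-effect weights.

    z = (b_a - b_b) / sqrt(var_a + var_b - 2 cov_ab), two-sided normal p.
    """
    for name in (name_a, name_b):
        if name not in fit.fixed_effects:
            raise KeyError(f"{name!r} not among fixed effects {list(fit.fixed_effects)}")
    if fit.fixed_cov is None:
        raise ValueError("fixed-effect covariance unavailable")
    est_a = fit.fixed_effects[name_a].estimate
    est_b = fit.fixed_effects[name_b].estimate
    var = (
        fit.fixed_cov.loc[name_a, name_a]
        + fit.fixed_cov.loc[name_b, name_b]
        - 2.0 * fit.fixed_cov.loc[name_a, name_b]
    )
    diff = est_a - est_b
    if var <= 0:
        z = float("inf") if diff != 0 else 0.0
    else:
        z = diff / math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return ContrastResult(pair=(name_a, name_b), beta_diff=diff, z=z, p=p)


def _informational_frame(
    trials: pd.DataFrame, roster: Sequence[Scenario], clip: float
) -> pd.DataFrame:
    """Per-trial confidence-in-most-likely-option rows.

    Tie policy: scenarios at posterior exactly 0.5 use disease A as the
    "most likely" reference side (recorded in the frame's attrs).
    """
    by_id = {s.id: s for s in roster}
    missing = [sid for sid in trials["scenario_id"].unique() if sid not in by_id]
    if missing:
        raise ScenarioJoinError(missing)
    rows = []
    for pid, sid, choice, conf in zip(
        trials["participant_id"], trials["scenario_id"],
        trials["choice"], trials["confidence"],
    ):
        scen = by_id[sid]
        ml = scen.most_likely
        target = Direction.A if ml is MostLikely.TIE else Direction(ml.value)
        c_ml = confidence_for_option(choice, conf, target) / 100.0
        c_ml = min(max(c_ml, clip), 1.0 - clip)
        advisors = scen.advisors
        prop_ai = sum(1 for a in advisors if a.kind is SourceKind.AI) / len(advisors)
        rows.append(
            {
                "participant_id": pid,
                "scenario_id": sid,
                "posterior": scen.posterior_favored,
                "prop_ai": prop_ai,
                "conf_ml": c_ml,
                "y": math.log(c_ml / (1.0 - c_ml)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["tie_policy"] = "A-side is the most-likely reference at posterior 0.5"
    return out


def fit_confidence_vs_posterior(
    trials: pd.DataFrame,
    roster: Sequence[Scenario],
    include_advisor_mix: bool = False,
    clip: float = 0.005,
    reml: bool = True,
    inference: str = "z",
    engine: str = "gaussian_logit",
) -> FitResult:
    """Informational-influence model: confidence vs posterior probability.

    Default engine is a Gaussian linear mixed model on logit-transformed
    confidence in the most likely diagnosis, with a per-participant random
    intercept and an independent random slope on the posterior.  With
    ``include_advisor_mix`` the advisor-type proportion and its
    interaction with the posterior enter as fixed effects; the interaction
    coefficient and the residual SD are the inputs to the equivalence
    (TOST) procedure.
    """
    if engine != "gaussian_logit":
        raise NotImplementedError(
            f"engine {engine!r} not available; use 'gaussian_logit'"
        )
    frame = _informational_frame(trials, roster, clip)
    formula = "y ~ posterior"
    if include_advisor_mix:
        formula += " + prop_ai + posterior:prop_ai"
    model = smf.mixedlm(
        formula,
        frame,
        groups=frame["participant_id"],
        re_formula="1",
        vc_formula={"posterior": "0 + posterior"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    n_participants = frame["participant_id"].nunique()
    return _extract_fit(
        result,
        {"Intercept": "intercept"},
        {"intercept": "intercept", "posterior": "posterior"},
        n_participants=n_participants,
        n_trials=len(frame),
        method="reml" if reml else "ml",
        inference=inference,
    )
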