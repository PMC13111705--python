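"""Descriptive and secondary analyses of cascade-trial data.

Covers four reporting surfaces of the studies: the informational-
influence curves (choice and confidence by posterior-probability level),
the normative-influence comparison on corroboration trials (population-
averaged GEE for choices, mixed model for confidence), ceiling
diagnostics for saturated confidence scales, and the varying-accuracy
majority × accuracy models.

All participant-level summaries aggregate within participant first and
across participants second; on unbalanced data this differs from pooling
trials, and the participant-first order is the one used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .design import (
    AccuracyCondition,
    Corroboration,
    Direction,
    MajorityKind,
    MostLikely,
    Scenario,
)
from .influence import ScenarioJoinError, confidence_for_option

__all__ = [
    "CeilingDiagnostics",
    "MajorityAnalysisResult",
    "curve_by_posterior",
    "select_normative_trials",
    "normative_comparison",
    "ceiling_diagnostics",
    "majority_models",
]


def _check_join(trials: pd.DataFrame, by_id: dict) -> None:
    missing = [sid for sid in trials["scenario_id"].unique() if sid not in by_id]
    if missing:
        raise ScenarioJoinError(missing)


def curve_by_posterior(
    trials: pd.DataFrame, roster: Sequence[Scenario]
) -> pd.DataFrame:
    """Choice and confidence in the most likely option, by posterior level.

    Aggregates per participant within each (2-dp rounded) posterior level
    first, then reports the mean and SD across participants.  Scenarios at
    posterior exactly 0.5 use the A side as the "most likely" reference
    (tie policy recorded in ``attrs``).
    """
    by_id = {s.id: s for s in roster}
    _check_join(trials, by_id)
    rows = []
    for pid, sid, choice, conf in zip(
        trials["participant_id"], trials["scenario_id"],
        trials["choice"], trials["confidence"],
    ):
        scen = by_id[sid]
        ml = scen.most_likely
        target = Direction.A if ml is MostLikely.TIE else Direction(ml.value)
        rows.append(
            {
                "participant_id": pid,
                "level": scen.posterior_level,
                "follow_ml": float(Direction(choice) == target),
                "conf_ml": confidence_for_option(choice, conf, target) / 100.0,
            }
        )
    df = pd.DataFrame(rows)
    per_part = (
        df.groupby(["level", "participant_id"])[["follow_ml", "conf_ml"]]
        .mean()
        .reset_index()
    )
    out = (
        per_part.groupby("level")
        .agg(
            choice_mean=("follow_ml", "mean"),
            choice_sd=("follow_ml", "std"),
            conf_mean=("conf_ml", "mean"),
            conf_sd=("conf_ml", "std"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
        .sort_values("level", ignore_index=True)
    )
    out.attrs["tie_policy"] = "A-side is the most-likely reference at posterior 0.5"
    return out


_KEEP = {
    Corroboration.HUMAN_CORROBORATES_PI: "human",
    Corroboration.AI_CORROBORATES_PI: "ai",
}


def select_normative_trials(
    trials: pd.DataFrame, roster: Sequence[Scenario]
) -> pd.DataFrame:
    """Subset to trials usable for the normative human-vs-AI comparison.

    Keeps trials whose advisors corroborate the private information
    through exactly one advisor type — dropping trials where the advice
    uniformly contradicts the symptom and trials where humans and AI give
    the same diagnosis — and labels each kept trial with the
    corroborating type.  Applying the selection twice is a no-op.
    """
    by_id = {s.id: s for s in roster}
    _check_join(trials, by_id)
    context = {sid: s.context() for sid, s in by_id.items()}
    labels = trials["scenario_id"].map(
        lambda sid: _KEEP.get(context[sid].corroboration)
    )
    out = trials.loc[labels.notna()].copy()
    out["corroborating_type"] = labels[labels.notna()]
    return out


def _cell_logodds_fallback(subset: pd.DataFrame) -> tuple[float, float]:
    """Continuity-corrected log-odds difference when GEE separates."""
    cells = subset.groupby("corroborating_type")["follow_pi"].agg(["sum", "count"])
    est, var = 0.0, 0.0
    for label, sign in (("human", 1.0), ("ai", -1.0)):
        s = cells.loc[label, "sum"] + 0.5
        f = cells.loc[label, "count"] - cells.loc[label, "sum"] + 0.5
        est += sign * math.log(s / f)
        var += 1.0 / s + 1.0 / f
    return est, math.sqrt(var)


def _fit_choice_gee(subset: pd.DataFrame, working_corr: str) -> dict:
    degenerate = subset["follow_pi"].nunique() < 2 or (
        subset.groupby("corroborating_type")["follow_pi"].nunique() < 2
    ).any()
    if degenerate:
        est, se = _cell_logodds_fallback(subset)
        z = est / se if se > 0 else float("nan")
        return {
            "estimate": est, "se": se, "stat": z,
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
            "separation": True,
        }
    cov = (
        sm.cov_struct.Exchangeable()
        if working_corr == "exchangeable"
        else sm.cov_struct.Independence()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.gee(
            "follow_pi ~ corroborating_human",
            groups="participant_id",
            data=subset,
            family=sm.families.Binomial(),
            cov_struct=cov,
        )
        res = model.fit()
    est = float(res.params["corroborating_human"])
    se = float(res.bse["corroborating_human"])
    return {
        "estimate": est, "se": se, "stat": est / se,
        "p": float(res.pvalues["corroborating_human"]),
        "separation": False,
    }


def _fit_conf_lmm(subset: pd.DataFrame) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "conf_pi ~ corroborating_human",
            subset,
            groups=subset["participant_id"],
        )
        res = model.fit(reml=True)
    est = float(res.fe_params["corroborating_human"])
    se = float(res.bse_fe["corroborating_human"])
    z = est / se if se > 0 else float("nan")
    return {
        "estimate": est, "se": se, "stat": z,
        "p": float(2 * stats.norm.sf(abs(z))),
        "separation": False,
    }


def normative_comparison(
    subset: pd.DataFrame,
    roster: Sequence[Scenario],
    working_corr: str = "exchangeable",
    per_level: bool = True,
) -> pd.DataFrame:
    """Human-vs-AI normative influence on corroboration trials.

    Binary follow-the-private-information outcome → population-averaged
    logistic GEE (participant clusters, exchangeable working correlation,
    robust SEs); confidence-in-the-private-information outcome → linear
    mixed model with a random participant intercept.  The advisor-type
    covariate codes the human-corroborating condition as 1 (AI = 0), so a
    positive coefficient means stronger normative pull from humans.
    Returns a tidy table of pooled and per-posterior-level effects;
    complete separation falls back to continuity-corrected cell odds with
    a flag.
    """
    if subset.empty or subset["corroborating_type"].nunique() < 2:
        raise ValueError(
            "normative comparison needs both human- and AI-corroborating trials"
        )
    by_id = {s.id: s for s in roster}
    _check_join(subset, by_id)
    df = subset.copy()
    pi_dir = df["scenario_id"].map(lambda sid: by_id[sid].private.direction)
    df["follow_pi"] = (
        df["choice"].map(Direction) == pi_dir
    ).astype(float)
    df["conf_pi"] = [
        confidence_for_option(c, conf, d) / 100.0
        for c, conf, d in zip(df["choice"], df["confidence"], pi_dir)
    ]
    df["corroborating_human"] = (df["corroborating_type"] == "human").astype(float)
    df["level"] = df["scenario_id"].map(lambda sid: by_id[sid].posterior_level)

    rows = []
    groups: list[tuple[str, pd.DataFrame]] = [("pooled", df)]
    if per_level:
        groups += [
            (f"{lvl:g}", g)
            for lvl, g in df.groupby("level")
            if g["corroborating_type"].nunique() == 2
        ]
    for label, g in groups:
        choice = _fit_choice_gee(g, working_corr)
        conf = _fit_conf_lmm(g)
        for outcome, res in (("choice", choice), ("confidence", conf)):
            rows.append({"level": label, "outcome": outcome, "n_trials": len(g), **res})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CeilingDiagnostics:
    """Saturation diagnostics for confidence ratings on (0, 1]."""

    skewness: float
    excess_kurtosis: float
    top_decile_share: float
    saturated: bool


def ceiling_diagnostics(confidences: Sequence[float]) -> CeilingDiagnostics:
    """Detect ceiling effects in confidence-in-most-likely ratings.

    Computes adjusted Fisher-Pearson sample skewness, excess kurtosis and
    the share of responses in the top decile [0.90, 1.00]; the scale is
    flagged saturated when skewness < -1.8, excess kurtosis > 2.5 and the
    top-decile share exceeds 50%.  A constant vector has undefined moments
    and yields NaN diagnostics with ``saturated=False``.
    """
    x = np.asarray(confidences, dtype=float)
    if x.size < 3:
        raise ValueError("ceiling diagnostics need at least 3 values")
    share = float(np.mean((x >= 0.90) & (x <= 1.00)))
    if np.ptp(x) == 0.0:
        return CeilingDiagnostics(float("nan"), float("nan"), share, False)
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    saturated = (skew < -1.8) and (kurt > 2.5) and (share > 0.5)
    return CeilingDiagnostics(skew, kurt, share, saturated)


@dataclass
class MajorityAnalysisResult:
    """Majority-following models for the varying-accuracy profile.

    ``choice_model`` is the binomial GLMM (logit link, random participant
    intercept) for following the majority; ``confidence_model`` the
    linear mixed model for confidence in the majority's diagnosis.  Both
    use AI and HIGH accuracy as reference levels, so the advisor-type
    term is the human-majority effect and the accuracy term the LOW-
    condition effect.  ``cell_means`` aggregates participant-first.
    """

    choice_model: pd.DataFrame
    confidence_model: pd.DataFrame
    cell_means: pd.DataFrame


def majority_models(
    trials: pd.DataFrame, roster: Sequence[Scenario]
) -> MajorityAnalysisResult:
    by_id = {s.id: s for s in roster}
    _check_join(trials, by_id)
    context = {sid: s.context() for sid, s in by_id.items()}

    rows = []
    for pid, sid, choice, conf in zip(
        trials["participant_id"], trials["scenario_id"],
        trials["choice"], trials["confidence"],
    ):
        ctx = context[sid]
        if ctx.majority_kind is MajorityKind.NONE:
            continue
        if ctx.majority_accuracy_condition is AccuracyCondition.NONE:
            continue
        scen = by_id[sid]
        maj_kind = ctx.majority_kind
        maj_dir = next(
            s.direction for s in scen.advisors if s.kind.value == maj_kind.value
        )
        rows.append(
            {
                "participant_id": pid,
                "follow_maj": float(Direction(choice) == maj_dir),
                "conf_maj": confidence_for_option(choice, conf, maj_dir) / 100.0,
                "majority_human": float(maj_kind is MajorityKind.HUMAN),
                "low_accuracy": float(
                    ctx.majority_accuracy_condition is AccuracyCondition.LOW
                ),
            }
        )
    df = pd.DataFrame(rows)
    expected = {(h, l) for h in (0.0, 1.0) for l in (0.0, 1.0)}
    present = set(map(tuple, df[["majority_human", "low_accuracy"]].drop_duplicates().to_numpy()))
    missing = expected - present
    if missing:
        raise ValueError(
            "missing advisor-type × accuracy cells: "
            + ", ".join(
                f"({'human' if h else 'ai'}, {'low' if l else 'high'})"
                for h, l in sorted(missing)
            )
        )

    # binomial GLMM with random participant intercepts (variational fit);
    # a constant outcome (e.g. everyone always follows the majority) has
    # no likelihood information about the effects — report it as separated
    terms = ["Intercept", "majority_human", "low_accuracy",
             "majority_human:low_accuracy"]
    if df["follow_maj"].nunique() < 2:
        nan = float("nan")
        choice_model = pd.DataFrame(
            [{"term": t, "estimate": nan, "se": nan, "stat": nan, "p": nan,
              "separation": True} for t in terms]
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glmm = sm.BinomialBayesMixedGLM.from_formula(
                "follow_maj ~ majority_human * low_accuracy",
                {"participant": "0 + C(participant_id)"},
                df,
            ).fit_vb()
        fe_names = list(glmm.model.exog_names)
        choice_rows = []
        for i, name in enumerate(fe_names):
            est, se = float(glmm.fe_mean[i]), float(glmm.fe_sd[i])
            z = est / se if se > 0 else float("nan")
            choice_rows.append(
                {"term": name, "estimate": est, "se": se, "stat": z,
                 "p": float(2 * stats.norm.sf(abs(z))), "separation": False}
            )
        choice_model = pd.DataFrame(choice_rows)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lmm = smf.mixedlm(
            "conf_maj ~ majority_human * low_accuracy",
            df,
            groups=df["participant_id"],
        ).fit(reml=True)
    conf_rows = []
    for name in lmm.fe_params.index:
        est, se = float(lmm.fe_params[name]), float(lmm.bse_fe[name])
        z = est / se if se > 0 else float("nan")
        conf_rows.append(
            {"term": name, "estimate": est, "se": se, "stat": z,
             "p": float(2 * stats.norm.sf(abs(z)))}
        )
    confidence_model = pd.DataFrame(conf_rows)

    per_part = (
        df.groupby(["majority_human", "low_accuracy", "participant_id"])[
            ["follow_maj", "conf_maj"]
        ]
        .mean()
        .reset_index()
    )
    cell_means = (
        per_part.groupby(["majority_human", "low_accuracy"])
        .agg(
            follow_mean=("follow_maj", "mean"),
            follow_sd=("follow_maj", "std"),
            conf_mean=("conf_maj", "mean"),
            conf_sd=("conf_maj", "std"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    cell_means["advisor_type"] = np.where(cell_means["majority_human"] == 1.0, "human", "ai")
    cell_means["accuracy"] = np.where(cell_means["low_accuracy"] == 1.0, "low", "high")
    return MajorityAnalysisResult(choice_model, confidence_model, cell_means)


def majority_anova(trials: pd.DataFrame, roster: Sequence[Scenario]) -> pd.DataFrame:
    """Preliminary two-way ANOVA over participant-level majority means.

    Convenience wrapper only: aggregates follow-majority and
    confidence-in-majority per participant × advisor-type × accuracy cell
    and runs standard OLS ANOVAs on the cell means.  The mixed models in
    :func:`majority_models` are the substantive analysis.
    """
    by_id = {s.id: s for s in roster}
    _check_join(trials, by_id)
    context = {sid: s.context() for sid, s in by_id.items()}
    rows = []
    for pid, sid, choice, conf in zip(
        trials["participant_id"], trials["scenario_id"],
        trials["choice"], trials["confidence"],
    ):
        ctx = context[sid]
        if ctx.majority_kind is MajorityKind.NONE:
            continue
        if ctx.majority_accuracy_condition is AccuracyCondition.NONE:
            continue
        scen = by_id[sid]
        maj_dir = next(
            s.direction for s in scen.advisors
            if s.kind.value == ctx.majority_kind.value
        )
        rows.append(
            {
                "participant_id": pid,
                "advisor_type": ctx.majority_kind.value,
                "accuracy": ctx.majority_accuracy_condition.value,
                "follow_maj": float(Direction(choice) == maj_dir),
                "conf_maj": confidence_for_option(choice, conf, maj_dir) / 100.0,
            }
        )
    per_part = (
        pd.DataFrame(rows)
        .groupby(["participant_id", "advisor_type", "accuracy"])[
            ["follow_maj", "conf_maj"]
        ]
        .mean()
        .reset_index()
    )
    out = []
    for outcome in ("follow_maj", "conf_maj"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(
                f"{outcome} ~ C(advisor_type) * C(accuracy)", per_part
            ).fit()
            table = sm.stats.anova_lm(ols, typ=2)
        table = table.reset_index().rename(columns={"index": "term"})
        table.insert(0, "outcome", outcome)
        out.append(table)
    return pd.concat(out, ignore_index=True)
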