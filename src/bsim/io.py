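"""Reading and validating long-format trial tables.

On disk a cohort is a CSV with one row per participant × scenario:
``participant_id, scenario_id, choice, confidence`` (choice in {A, S},
confidence as integer percent in [50, 100]).  Confidence is stored as
percent in files and converted to fractions only inside the analyses.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .design import Scenario
from .influence import ScenarioJoinError

__all__ = ["TrialValidationError", "read_trials", "write_trials"]

REQUIRED_COLUMNS = ["participant_id", "scenario_id", "choice", "confidence"]


class TrialValidationError(ValueError):
    """Schema violations, with the offending 0-based row indices."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid trial table:\n  " + "\n  ".join(problems[:20]))


def validate_trials(
    df: pd.DataFrame, roster: Sequence[Scenario] | None = None
) -> pd.DataFrame:
    problems: list[str] = []
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialValidationError([f"missing columns: {missing_cols}"])

    bad_choice = df.index[~df["choice"].isin(["A", "S"])]
    if len(bad_choice):
        problems.append(f"choice not in {{A, S}} at rows {list(bad_choice[:10])}")

    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad_conf = df.index[conf.isna() | (conf < 50) | (conf > 100)]
    if len(bad_conf):
        problems.append(
            f"confidence outside [50, 100] at rows {list(bad_conf[:10])}"
        )

    dup = df.duplicated(subset=["participant_id", "scenario_id"], keep=False)
    if dup.any():
        problems.append(
            "duplicated participant × scenario at rows "
            f"{list(df.index[dup][:10])} (each participant answers each "
            "scenario once)"
        )
    if problems:
        raise TrialValidationError(problems)

    out = df.copy()
    out["confidence"] = conf.astype(int)
    if roster is not None:
        known = {s.id for s in roster}
        unknown = [sid for sid in out["scenario_id"].unique() if sid not in known]
        if unknown:
            raise ScenarioJoinError(unknown)
    return out


def read_trials(
    path: str | Path, roster: Sequence[Scenario] | None = None
) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    With a roster, scenario ids are checked to resolve against it.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "scenario_id": str})
    return validate_trials(df, roster)


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV plus a metadata sidecar JSON if present."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = df.attrs.get("metadata")
    if meta is not None:
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
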