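"""Trial-table containers and the canonical CSV format.

One row per trial:

``participant_id, trial_index, trial_type, x1, p1, x2, p2, x3, p3, chosen``

``trial_type`` is ``two_option`` or ``distractor``; options 1 and 2 are the
chooseable options, option 3 the distractor (blank on two-option rows);
``chosen`` is 1, 2 or 3, with 0 marking a missed / empty-quadrant response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "TWO_OPTION",
    "DISTRACTOR",
    "MISSED",
    "TrialTableError",
    "ChoiceDataset",
    "read_trial_table",
    "write_trial_table",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "trial_type",
    "x1",
    "p1",
    "x2",
    "p2",
    "x3",
    "p3",
    "chosen",
]

TWO_OPTION = "two_option"
DISTRACTOR = "distractor"
#: sentinel chosen-code for missed / empty-quadrant responses
MISSED = 0


class TrialTableError(ValueError):
    """Schema or row-level validation failure in a trial table."""


@dataclass
class ChoiceDataset:
    """One participant's trial table plus bookkeeping metadata.

    ``trials`` holds columns ``trial_type, x1, p1, x2, p2, x3, p3, chosen``
    in presentation order; ``x3``/``p3`` are NaN on two-option rows.
    """

    participant_id: str
    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"trial_type", "x1", "p1", "x2", "p2", "x3", "p3", "chosen"}
        missing = required - set(self.trials.columns)
        if missing:
            raise TrialTableError(f"trial table missing columns: {sorted(missing)}")
        _validate_rows(self.trials, self.participant_id)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def two_option_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == TWO_OPTION]

    def distractor_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == DISTRACTOR]

    def equals(self, other: "ChoiceDataset") -> bool:
        if self.participant_id != other.participant_id:
            return False
        a = self.trials.reset_index(drop=True)
        b = other.trials.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if a[col].dtype.kind == "f" or b[col].dtype.kind == "f":
                av = a[col].to_numpy(dtype=float)
                bv = b[col].to_numpy(dtype=float)
                if not np.allclose(av, bv, equal_nan=True):
                    return False
            elif not (a[col] == b[col]).all():
                return False
        return True


def _validate_rows(df: pd.DataFrame, participant_id: str) -> None:
    for pos, (idx, row) in enumerate(df.iterrows()):
        label = f"participant {participant_id!r} row {pos}"
        ttype = row["trial_type"]
        if ttype not in (TWO_OPTION, DISTRACTOR):
            raise TrialTableError(f"{label}: unknown trial_type {ttype!r}")
        cols = ["x1", "p1", "x2", "p2"] + (["x3", "p3"] if ttype == DISTRACTOR else [])
        for col in cols:
            v = row[col]
            if pd.isna(v) or not (0.0 <= float(v) <= 1.0):
                raise TrialTableError(f"{label}: {col}={v!r} outside [0, 1]")
        if ttype == TWO_OPTION and not (
            pd.isna(row["x3"]) and pd.isna(row["p3"])
        ):
            raise TrialTableError(f"{label}: two_option rows must leave x3/p3 empty")
        chosen = int(row["chosen"])
        valid = (MISSED, 1, 2, 3) if ttype == DISTRACTOR else (MISSED, 1, 2)
        if chosen not in valid:
            raise TrialTableError(f"{label}: chosen={chosen} invalid on {ttype} trial")


def read_trial_table(path: Union[str, Path]) -> list[ChoiceDataset]:
    """Read the canonical trial-table CSV into one ChoiceDataset per participant.

    Row order within a participant is preserved.  Raises
    :class:`TrialTableError` naming the offending column or row on any
    schema violation.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path.name}: missing columns {missing}")
    datasets = []
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("trial_index", kind="stable")
        trials = sub[["trial_type", "x1", "p1", "x2", "p2", "x3", "p3", "chosen"]].reset_index(
            drop=True
        )
        trials["chosen"] = trials["chosen"].astype(int)
        datasets.append(ChoiceDataset(participant_id=str(pid), trials=trials))
    return datasets


def write_trial_table(datasets: Iterable[ChoiceDataset], path: Union[str, Path]) -> None:
    """Write ChoiceDatasets to the canonical CSV (comma, UTF-8, '.' decimal)."""
    frames = []
    for ds in datasets:
        out = ds.trials.copy()
        out.insert(0, "participant_id", ds.participant_id)
        out.insert(1, "trial_index", np.arange(len(out)))
        frames.append(out[TRIAL_COLUMNS])
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRIAL_COLUMNS)
    table.to_csv(path, index=False)
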