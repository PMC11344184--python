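"""Long-format choice data: dummy coding, validation, I/O, sample summaries.

The estimation input is one row per respondent × choice task × alternative.
Designed alternatives carry a vaccination constant of 1 plus the dummy and
price covariates of their profile; the opt-out row is all zeros (its
utility anchors the scale, so the constant is the preference for being
vaccinated at all, relative to no vaccination).  Exactly one row per
(respondent, task) group has ``chosen = 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import (
    CATEGORICAL,
    CONSTANT_NAME,
    CONTINUOUS,
    OPTOUT_ID,
    Profile,
    StudyDesignSpec,
    validate_profile,
)
from .errors import InvalidSpecError, ValidationError

logger = logging.getLogger(__name__)

ID_COLUMNS = ["respondent_id", "task_id", "alt_id", "chosen"]


def encode_profile(profile: Profile, spec: StudyDesignSpec) -> dict[str, float]:
    """Covariate values of a profile under the study's coding scheme.

    Non-reference categorical levels map to a 1 in their indicator column;
    reference levels contribute nothing; continuous attributes (price) map
    to their numeric value.  Column order follows
    :meth:`StudyDesignSpec.coefficient_columns`.
    """
    validate_profile(profile, spec)
    values: dict[str, float] = {}
    for a in spec.attributes:
        lv = profile.level(a.name)
        if a.coding == CONTINUOUS:
            values[a.column_names()[0]] = a.numeric_value(lv)
        else:
            for other, col in a.dummy_columns():
                values[col] = 1.0 if lv == other else 0.0
    return values


def decode_profile(values: Mapping[str, float], spec: StudyDesignSpec) -> Profile:
    """Inverse of :func:`encode_profile` (categorical levels recovered from
    dummies, continuous levels matched by numeric value)."""
    assignment = {}
    for a in spec.attributes:
        if a.coding == CONTINUOUS:
            x = float(values[a.column_names()[0]])
            matches = [lv for lv in a.levels if a.numeric_value(lv) == x]
            if not matches:
                raise InvalidSpecError(
                    f"value {x} matches no level of continuous attribute {a.name!r}"
                )
            assignment[a.name] = matches[0]
        else:
            hot = [lv for lv, col in a.dummy_columns() if values.get(col, 0.0) == 1.0]
            if len(hot) > 1:
                raise InvalidSpecError(f"multiple dummies set for attribute {a.name!r}")
            assignment[a.name] = hot[0] if hot else a.reference_level
    return Profile.from_mapping(assignment)


@dataclass
class LongChoiceTable:
    """Validated long-format choice data plus study metadata.

    ``data`` holds the id columns (respondent_id, task_id, alt_id, chosen,
    optionally block_id), the vaccination constant and the coded covariates.
    ``demographics`` is an optional one-row-per-respondent frame.
    """

    data: pd.DataFrame
    spec: StudyDesignSpec
    demographics: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def coefficient_columns(self) -> list[str]:
        return self.spec.coefficient_columns()

    @property
    def n_respondents(self) -> int:
        return self.data["respondent_id"].nunique()

    @property
    def n_tasks(self) -> int:
        return len(self.data.groupby(["respondent_id", "task_id"], sort=False))

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        missing = [c for c in ID_COLUMNS + self.coefficient_columns if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        if not df["chosen"].isin([0, 1]).all():
            raise ValidationError("chosen must be 0/1")

        per_task = df.groupby(["respondent_id", "task_id"])["chosen"].sum()
        bad = per_task[per_task != 1]
        if len(bad):
            examples = ", ".join(
                f"(respondent {r}, task {t}): {int(k)} chosen"
                for (r, t), k in bad.head(10).items()
            )
            raise ValidationError(
                f"{len(bad)} (respondent, task) groups without exactly one "
                f"chosen alternative: {examples}"
            )

        dummy_cols = [
            col for a in self.spec.attributes if a.coding == CATEGORICAL
            for _, col in a.dummy_columns()
        ]
        for col in dummy_cols:
            if not df[col].isin([0, 1]).all():
                raise ValidationError(f"dummy column {col!r} must be 0/1")
        for a in self.spec.attributes:
            if a.coding == CATEGORICAL and a.n_levels > 2:
                cols = [c for _, c in a.dummy_columns()]
                if (df[cols].sum(axis=1) > 1).any():
                    raise ValidationError(
                        f"more than one dummy set for attribute {a.name!r}"
                    )

        optout = df[df["alt_id"] == OPTOUT_ID]
        if len(optout):
            cov = optout[[CONSTANT_NAME] + self.coefficient_columns[1:]]
            if (cov.to_numpy() != 0).any():
                raise ValidationError("opt-out rows must have all covariates zero")
        designed = df[df["alt_id"] != OPTOUT_ID]
        if len(designed) and not (designed[CONSTANT_NAME] == 1).all():
            raise ValidationError("designed rows must carry a vaccination constant of 1")

        if "block_id" in df.columns:
            per_resp = df.groupby("respondent_id")["block_id"].nunique()
            if (per_resp > 1).any():
                bad_r = per_resp[per_resp > 1].index.tolist()[:10]
                raise ValidationError(
                    f"respondents spanning multiple blocks: {bad_r}"
                )

    # -- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path, spec: StudyDesignSpec,
             demographics: pd.DataFrame | None = None,
             strict: bool = True) -> "LongChoiceTable":
        df = pd.read_csv(path)
        if not strict:
            per_task = df.groupby(["respondent_id", "task_id"])["chosen"].transform("sum")
            dropped = int((per_task == 0).sum())
            if dropped:
                n_tasks = df[per_task == 0].groupby(
                    ["respondent_id", "task_id"]).ngroups
                logger.warning("dropping %d tasks (%d rows) with no chosen alternative",
                               n_tasks, dropped)
                df = df[per_task > 0].reset_index(drop=True)
        return cls(df, spec, demographics)


def load_choice_table(path: str | Path, spec: StudyDesignSpec,
                      strict: bool = True) -> LongChoiceTable:
    """Read and validate a long-format choice table from delimited text."""
    return LongChoiceTable.read(path, spec, strict=strict)


def write_choice_table(table: LongChoiceTable, path: str | Path) -> None:
    table.write(path)


def summarize_sample(demographics: pd.DataFrame,
                     characteristics: Iterable[str] | None = None) -> pd.DataFrame:
    """Frequency table of respondent characteristics: n and percent.

    Percentages are within-characteristic, rounded to 2 decimals (e.g.
    1746 female of 2864 respondents → 60.96).
    """
    if demographics is None or len(demographics) == 0:
        raise ValidationError("demographics are empty")
    if characteristics is None:
        characteristics = [c for c in demographics.columns if c != "respondent_id"]
    rows = []
    for char in characteristics:
        col = demographics[char]
        counts = col.value_counts(sort=False)
        if not isinstance(col.dtype, pd.CategoricalDtype):
            counts = counts.loc[col.drop_duplicates()]  # order of appearance
        total = int(counts.sum())
        for category, n in counts.items():
            rows.append({
                "characteristic": char,
                "category": category,
                "n": int(n),
                "percent": round(100.0 * n / total, 2),
            })
    return pd.DataFrame(rows)
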