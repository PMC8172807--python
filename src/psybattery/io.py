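"""CSV survey reading/writing and frame <-> response conversion.

The on-disk format is one row per survey: ``year``, ``age`` (integer years
or one of the two categorical extremes), ``gender``, then one column per
instrument item named ``<scale>_q<k>`` holding the 0-based printed answer
index; empty cells are unanswered items.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import (
    AGE_HIGH_TEXT,
    AGE_LOW_TEXT,
    GENDERS,
    SCALES,
    SurveyResponse,
    YEARS,
    item_columns,
)

logger = logging.getLogger(__name__)

META_COLUMNS = ["year", "age", "gender"]

_AGE_TEXT = re.compile(r"^(\d+)\s*years?$")


def parse_age(value) -> int | str:
    """Parse an age cell to an integer, keeping the categorical extremes."""
    if isinstance(value, str):
        text = value.strip()
        if text in (AGE_LOW_TEXT, AGE_HIGH_TEXT):
            return text
        m = _AGE_TEXT.match(text)
        if m:
            return int(m.group(1))
        return int(text)  # raises ValueError on garbage
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError("missing age")
    return int(value)


def read_surveys(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey CSV; malformed rows raise."""
    df = pd.read_csv(path, dtype={"age": "object", "gender": "object"})
    return validate_frame(df)


def validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    out = df.copy()
    bad_year = ~out["year"].astype(int).isin(YEARS)
    if bad_year.any():
        raise ValueError(f"invalid year in rows {list(out.index[bad_year])[:5]}")
    out["year"] = out["year"].astype(int)

    out["age"] = out["age"].map(parse_age)

    bad_gender = ~out["gender"].isin(GENDERS)
    if bad_gender.any():
        raise ValueError(
            f"unknown gender in rows {list(out.index[bad_gender])[:5]}"
        )

    known = set(item_columns())
    for col in out.columns:
        if col in META_COLUMNS:
            continue
        if col not in known:
            logger.warning("ignoring unknown column %r", col)
            continue
        sid, item = col.rsplit("_q", 1)
        levels = SCALES[sid].levels[int(item)]
        vals = pd.to_numeric(out[col], errors="raise").astype(float)
        present = vals.notna()
        bad = present & ((vals < 0) | (vals >= levels) | (vals % 1 != 0))
        if bad.any():
            raise ValueError(
                f"{col}: answer index out of range in rows "
                f"{list(out.index[bad])[:5]}"
            )
        out[col] = vals
    return out


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def responses_to_frame(responses: list[SurveyResponse]) -> pd.DataFrame:
    cols = item_columns()
    rows = []
    for r in responses:
        row = {"year": r.year, "age": r.age, "gender": r.gender}
        for (sid, item), idx in r.answers.items():
            row[f"{sid}_q{item}"] = float(idx)
        rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + cols)
    return df


def frame_to_responses(df: pd.DataFrame) -> list[SurveyResponse]:
    cols = [c for c in df.columns if c not in META_COLUMNS]
    parsed = [(c, *c.rsplit("_q", 1)) for c in cols]
    out = []
    for _, row in df.iterrows():
        answers = {}
        for col, sid, item in parsed:
            v = row[col]
            if pd.notna(v):
                answers[(sid, int(item))] = int(v)
        out.append(
            SurveyResponse(
                year=int(row["year"]),
                age=row["age"],
                gender=row["gender"],
                answers=answers,
            )
        )
    return out
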