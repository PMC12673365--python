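"""Objective synesthete classification from repeat-presentation consistency.

Each of the five original instrument tones is presented twice; the CIEDE2000
distance between the two picked colors measures how consistently that timbre
maps to a color for a subject. The per-subject score is the mean ΔE over the
instruments with a valid repeat pair (missing repeats drop out of both the
numerator and the denominator). Grade bands on the mean:

* [0, 10)  — excellent
* [10, 13) — very well
* [13, 16) — satisfactory
* ≥ 16     — poor, i.e. no timbre-color synesthesia

Subjects graded better than "poor" form the synesthete group; at ≥16 ΔE two
colors are considered different colors, so such subjects did not re-see "the
same" color for the same sound.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .colorspace import (
    ColorRGB,
    delta_e_ciede2000,
    hex_to_rgb,
    rgb_to_hex,
    rgb_to_hsl,
    srgb_to_lab,
)

__all__ = [
    "Grade",
    "SubjectScore",
    "load_responses",
    "responses_to_csv",
    "repeat_distance",
    "score_subject",
    "classify_grade",
    "score_table",
    "partition_groups",
]

#: Upper edges of the grade bands (half-open, breakpoints at 10/13/16 ΔE).
GRADE_EDGES = (10.0, 13.0, 16.0)


class Grade(enum.Enum):
    EXCELLENT = "excellent"
    VERY_WELL = "very_well"
    SATISFACTORY = "satisfactory"
    POOR = "poor"


@dataclass(frozen=True)
class SubjectScore:
    subject_id: str
    per_instrument_de: dict[str, float]  # NaN = missing repeat
    total_de: float
    n_valid: int
    mean_de: float
    grade: Grade

    @property
    def is_synesthete(self) -> bool:
        return self.grade is not Grade.POOR


_RESPONSE_COLUMNS = ["subject_id", "stimulus_id", "presentation", "r", "g", "b"]


def _validate(responses: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("subject_id", "stimulus_id", "presentation") if c not in responses.columns]
    if missing:
        raise ValueError(f"response table lacks columns {missing}")
    if responses.duplicated(["subject_id", "stimulus_id", "presentation"]).any():
        raise ValueError("duplicate (subject, stimulus, presentation) rows")
    return responses


def load_responses(path_or_buffer) -> pd.DataFrame:
    """Read a response CSV; accepts hex and/or r,g,b columns, rebuilds both.

    Expected schema: subject_id, stimulus_id, presentation, and either a
    ``hex`` column (#RRGGBB) or integer r,g,b columns; a true ``missing``
    flag marks absent responses. h,s,l columns are derived if absent.
    """
    df = pd.read_csv(path_or_buffer, dtype={"subject_id": str, "stimulus_id": str})
    if "missing" not in df.columns:
        df["missing"] = False
    df["missing"] = df["missing"].astype(bool)
    have_rgb = {"r", "g", "b"}.issubset(df.columns)
    if not have_rgb and "hex" in df.columns:
        rgb = df["hex"].map(lambda s: hex_to_rgb(s) if isinstance(s, str) else None)
        df["r"] = [c.r if c else np.nan for c in rgb]
        df["g"] = [c.g if c else np.nan for c in rgb]
        df["b"] = [c.b if c else np.nan for c in rgb]
    elif not have_rgb:
        raise ValueError("response table needs r,g,b or hex columns")
    if "hex" not in df.columns:
        df["hex"] = [
            rgb_to_hex(ColorRGB(int(r), int(g), int(b))) if not m else ""
            for r, g, b, m in zip(df["r"], df["g"], df["b"], df["missing"])
        ]
    if not {"h", "s", "l"}.issubset(df.columns):
        hsl = [
            rgb_to_hsl(ColorRGB(int(r), int(g), int(b))) if not m else None
            for r, g, b, m in zip(df["r"], df["g"], df["b"], df["missing"])
        ]
        df["h"] = [c.h if c else np.nan for c in hsl]
        df["s"] = [c.s if c else np.nan for c in hsl]
        df["l"] = [c.l if c else np.nan for c in hsl]
    return _validate(df)


def responses_to_csv(responses: pd.DataFrame, path) -> None:
    """Serialize with both hex and h,s,l columns so either can be read back."""
    cols = [c for c in _RESPONSE_COLUMNS + ["hex", "h", "s", "l", "missing"] if c in responses.columns]
    responses[cols].to_csv(path, index=False)


def repeat_distance(responses: pd.DataFrame, subject_id: str, stimulus_id: str) -> float:
    """ΔE between the two presentations of an original stimulus; NaN if a
    presentation is absent or flagged missing."""
    rows = responses[
        (responses["subject_id"] == subject_id) & (responses["stimulus_id"] == stimulus_id)
    ]
    if len(rows) > 2:
        raise ValueError(
            f"{len(rows)} presentations of {stimulus_id!r} for subject {subject_id!r}; expected <= 2"
        )
    if len(rows) < 2 or rows["missing"].any():
        return float("nan")
    labs = [
        srgb_to_lab(ColorRGB(int(r.r), int(r.g), int(r.b)))
        for r in rows.sort_values("presentation").itertuples()
    ]
    return delta_e_ciede2000(labs[0], labs[1])


def classify_grade(mean_de: float) -> Grade:
    if mean_de < 0 or math.isnan(mean_de):
        raise ValueError(f"mean ΔE must be nonnegative, got {mean_de}")
    for edge, grade in zip(GRADE_EDGES, (Grade.EXCELLENT, Grade.VERY_WELL, Grade.SATISFACTORY)):
        if mean_de < edge:
            return grade
    return Grade.POOR


def score_subject(subject_id: str, per_instrument: Mapping[str, float]) -> SubjectScore:
    """Aggregate per-instrument repeat ΔE into the consistency score.

    Missing (NaN) entries are excluded from both the sum and the divisor.
    """
    values = {k: float(v) for k, v in per_instrument.items()}
    valid = [v for v in values.values() if not math.isnan(v)]
    if not valid:
        raise ValueError(f"subject {subject_id!r} has no valid repeat pair; unscorable")
    if any(v < 0 for v in valid):
        raise ValueError("ΔE values must be nonnegative")
    total = float(sum(valid))
    mean = total / len(valid)
    return SubjectScore(subject_id, values, total, len(valid), mean, classify_grade(mean))


def score_table(
    responses: pd.DataFrame, instruments: Iterable[str], stimulus_of: Mapping[str, str] | None = None
) -> list[SubjectScore]:
    """Score every subject from a response table.

    ``stimulus_of`` maps instrument name -> original-stimulus id; defaults to
    ``f"{instrument}_orig"``.
    """
    stimulus_of = stimulus_of or {i: f"{i}_orig" for i in instruments}
    scores = []
    for subject_id in pd.unique(responses["subject_id"]):
        per = {
            inst: repeat_distance(responses, subject_id, stim)
            for inst, stim in stimulus_of.items()
        }
        scores.append(score_subject(subject_id, per))
    return scores


def partition_groups(
    scores: Iterable[SubjectScore],
) -> tuple[list[SubjectScore], list[SubjectScore], dict[Grade, int]]:
    """(synesthetes, non_synesthetes, grade census). Synesthete = not poor."""
    scores = list(scores)
    syn = [s for s in scores if s.is_synesthete]
    non = [s for s in scores if not s.is_synesthete]
    census = {g: 0 for g in Grade}
    for s in scores:
        census[s.grade] += 1
    return syn, non, census


def scores_to_frame(scores: Iterable[SubjectScore], instruments: Iterable[str]) -> pd.DataFrame:
    """Report table shaped like the published consistency table."""
    instruments = list(instruments)
    rows = []
    for s in scores:
        row = {"subject_id": s.subject_id}
        row.update({i: s.per_instrument_de.get(i, float("nan")) for i in instruments})
        row.update(
            {"total": s.total_de, "n_valid": s.n_valid, "mean": s.mean_de, "grade": s.grade.value}
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
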