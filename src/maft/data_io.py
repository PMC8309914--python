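"""Canonical in-memory data model and CSV I/O for AVEC-style feature streams.

A cohort consists of subjects, each carrying a PHQ-8 depression score in
[0, 24] and one frame-level numeric matrix (t frames x d dimensions) per
feature type.  Feature matrices arrive as openSMILE/openFace-style CSV
exports: one row per frame, numeric columns, optionally preceded by
non-numeric bookkeeping columns (frame index, timestamp) that the caller
declares and we skip.

Severity classes follow the standard PHQ-8 clinical cut-points at
0, 5, 10, 15 and 20: minimal [0-4], mild [5-9], moderate [10-14],
moderately severe [15-19] and severe [20-24].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lower edges of the five PHQ-8 severity classes.
PHQ8_CUTPOINTS = (0, 5, 10, 15, 20)

SEVERITY_NAMES = ("minimal", "mild", "moderate", "moderately severe", "severe")

LABEL_COLUMNS = ("Participant_ID", "PHQ8_Score", "PHQ8_Binary", "Gender")


class FeatureLevel(str, Enum):
    """Abstraction level of a feature stream.

    Low-level descriptors (MFCC, eGeMAPS, action units) are dense
    frame-rate streams tens of thousands of frames long; middle-level
    (bag-of-words) encodings are coarser; high-level (deep network)
    representations are short.  The level selects which frame-sampling
    budget applies downstream.
    """

    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"


class FormatError(ValueError):
    """Malformed on-disk input (ragged rows, non-numeric cells, ...)."""


class ValidationError(ValueError):
    """Semantically invalid input (score out of range, duplicate id, ...)."""


@dataclass
class FeatureSequence:
    """One feature type's frame matrix for one subject."""

    feature_name: str
    level: FeatureLevel
    frames: np.ndarray  # (t, d) float64

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1 or self.frames.shape[1] < 1:
            raise ValidationError(
                f"feature {self.feature_name!r}: frames must be a t x d matrix "
                f"with t, d >= 1, got shape {self.frames.shape}"
            )
        if not np.isfinite(self.frames).all():
            raise ValidationError(
                f"feature {self.feature_name!r}: non-finite entries in frame matrix"
            )
        self.level = FeatureLevel(self.level)

    @property
    def t(self) -> int:
        return self.frames.shape[0]

    @property
    def d(self) -> int:
        return self.frames.shape[1]


@dataclass
class SubjectRecord:
    """One interview subject: labels plus a map of feature streams."""

    subject_id: str
    phq8_score: int
    phq8_binary: int
    gender: str
    features: dict[str, FeatureSequence] = field(default_factory=dict)
    severity_class: int = field(init=False)

    def __post_init__(self) -> None:
        self.phq8_score = int(self.phq8_score)
        self.severity_class = bin_phq8(self.phq8_score)
        if self.phq8_binary not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id!r}: PHQ8_Binary must be 0 or 1"
            )


@dataclass
class LabelTable:
    """Validated label rows: one (id, score, binary, gender) per subject."""

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return self.frame.itertuples(index=False)


def bin_phq8(score: int) -> int:
    """Map a PHQ-8 score in [0, 24] to its 5-class severity label.

    Classes are closed integer ranges: 0 minimal [0-4], 1 mild [5-9],
    2 moderate [10-14], 3 moderately severe [15-19], 4 severe [20-24].
    """
    score = int(score)
    if not 0 <= score <= 24:
        raise ValidationError(f"PHQ-8 score {score} outside [0, 24]")
    return int(np.searchsorted(PHQ8_CUTPOINTS, score, side="right")) - 1


def read_feature_csv(
    path: str | Path,
    feature_name: str,
    level: FeatureLevel | str,
    *,
    skip_columns: int = 0,
    header: bool = False,
    delimiter: str = ",",
) -> FeatureSequence:
    """Read a frame-per-row numeric CSV into a FeatureSequence.

    Parameters
    ----------
    skip_columns
        Number of leading non-numeric bookkeeping columns (frame index,
        timestamp) to drop.  Declared explicitly rather than auto-detected.
    header
        Whether the first line is a header row.
    delimiter
        Field separator; openSMILE exports use ``,`` or ``;``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty feature file") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows ({exc})") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    if df.isna().any().any():
        # pandas fills short rows with NaN; report the first offending row
        row = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: ragged row at data row {row}")
    if skip_columns >= df.shape[1]:
        raise FormatError(
            f"{path}: skip_columns={skip_columns} leaves no numeric columns"
        )
    numeric = df.iloc[:, skip_columns:]
    try:
        frames = numeric.astype(np.float64).to_numpy()
    except ValueError:
        bad = numeric.apply(pd.to_numeric, errors="coerce")
        row = int(bad.isna().any(axis=1).idxmax())
        raise FormatError(
            f"{path}: non-numeric cell in numeric region at data row {row}"
        ) from None
    if not np.isfinite(frames).all():
        raise FormatError(f"{path}: non-finite values in feature matrix")
    return FeatureSequence(feature_name=feature_name, level=level, frames=frames)


def write_feature_csv(seq: FeatureSequence, path: str | Path) -> None:
    """Write the frame matrix as a bare numeric CSV (round-trips exactly)."""
    np.savetxt(path, seq.frames, delimiter=",", fmt="%.17g")


def read_label_table(path: str | Path) -> LabelTable:
    """Read and validate the label CSV.

    Expects columns ``Participant_ID, PHQ8_Score, PHQ8_Binary, Gender``.
    """
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: label table missing columns {missing}")
    df = df.loc[:, list(LABEL_COLUMNS)].copy()
    df["Participant_ID"] = df["Participant_ID"].astype(str)
    df["PHQ8_Score"] = df["PHQ8_Score"].astype(int)
    df["PHQ8_Binary"] = df["PHQ8_Binary"].astype(int)
    dupes = df["Participant_ID"][df["Participant_ID"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate subject ids: {sorted(set(dupes))}")
    bad = df[(df["PHQ8_Score"] < 0) | (df["PHQ8_Score"] > 24)]
    if len(bad):
        raise ValidationError(
            "PHQ-8 score outside [0, 24] for subjects: "
            f"{bad['Participant_ID'].tolist()}"
        )
    return LabelTable(frame=df.reset_index(drop=True))


def write_label_table(table: LabelTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def subjects_from_labels(table: LabelTable) -> list[SubjectRecord]:
    """Materialize SubjectRecords (without features) from a label table."""
    return [
        SubjectRecord(
            subject_id=row.Participant_ID,
            phq8_score=row.PHQ8_Score,
            phq8_binary=row.PHQ8_Binary,
            gender=row.Gender,
        )
        for row in table
    ]


def subjects_with_feature(
    subjects: list[SubjectRecord], feature_name: str
) -> list[SubjectRecord]:
    """Subjects carrying ``feature_name``; missing subjects are logged, not fatal.

    Per-feature models are independent, so a subject lacking one stream is
    simply excluded from that stream's model.
    """
    kept = [s for s in subjects if feature_name in s.features]
    dropped = [s.subject_id for s in subjects if feature_name not in s.features]
    if dropped:
        logger.warning(
            "feature %r missing for %d subject(s): %s",
            feature_name, len(dropped), dropped,
        )
    return kept
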