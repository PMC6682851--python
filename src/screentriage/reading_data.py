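"""Data model and tabular I/O for exams, readings and the study design.

The central container is :class:`ReadingDataset`, which holds an exam table,
a reading table and the score scales referenced by the readings.  All tabular
I/O is UTF-8 CSV with a header row.

Column contracts
----------------
``exams.csv``
    ``exam_id, study_id, truth, ai_category, raw_score`` where ``truth`` is
    one of ``normal``/``benign``/``cancer``; ``ai_category`` (integer 1-10)
    and ``raw_score`` (float) are individually optional but at least one must
    be present per exam.

``readings.csv``
    ``exam_id, reader_id, study_id, score, scale_min, scale_max``.

For all ROC computations, positives are ``cancer`` exams and negatives are
``normal`` and ``benign`` exams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

TRUTH_LABELS = ("normal", "benign", "cancer")

EXAM_COLUMNS = ("exam_id", "study_id", "truth", "ai_category", "raw_score")
READING_COLUMNS = ("exam_id", "reader_id", "study_id", "score", "scale_min", "scale_max")

_EXAM_REQUIRED = ("exam_id", "study_id", "truth")
_READING_REQUIRED = READING_COLUMNS


@dataclass(frozen=True)
class ScoreScale:
    """An ordered malignancy-score scale with inclusive numeric bounds."""

    scale_id: str
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValidationError(
                f"scale {self.scale_id!r}: minimum ({self.minimum}) must be "
                f"strictly below maximum ({self.maximum})"
            )

    @classmethod
    def from_bounds(cls, minimum: float, maximum: float) -> "ScoreScale":
        return cls(f"{minimum:g}:{maximum:g}", float(minimum), float(maximum))


@dataclass(frozen=True)
class ExamRecord:
    """One exam: ground truth, study block and AI score (category or raw)."""

    exam_id: str
    study_id: str
    truth: str
    ai_category: int | None = None
    raw_score: float | None = None

    def __post_init__(self) -> None:
        if self.truth not in TRUTH_LABELS:
            raise ValidationError(
                f"exam {self.exam_id!r}: unknown truth label {self.truth!r}"
            )
        if self.ai_category is None and self.raw_score is None:
            raise ValidationError(
                f"exam {self.exam_id!r}: needs ai_category or raw_score"
            )
        if self.ai_category is not None and not 1 <= int(self.ai_category) <= 10:
            raise ValidationError(
                f"exam {self.exam_id!r}: ai_category {self.ai_category} outside [1, 10]"
            )


@dataclass(frozen=True)
class ReadingRecord:
    """One radiologist interpretation of one exam."""

    exam_id: str
    reader_id: str
    study_id: str
    score: float
    scale_id: str


def binary_truth(exam: ExamRecord | str) -> bool:
    """ROC ground truth: ``True`` for cancer, ``False`` for benign/normal."""
    label = exam.truth if isinstance(exam, ExamRecord) else exam
    if label not in TRUTH_LABELS:
        raise ValidationError(f"unknown truth label {label!r}")
    return label == "cancer"


@dataclass
class ReadingDataset:
    """Exams, readings and scales, with the reader-by-exam design implied.

    ``exams`` and ``readings`` are pandas DataFrames following the CSV column
    contracts.  Scales are stored per reading row (``scale_min``/``scale_max``
    columns) and also collected in :attr:`scales`.
    """

    exams: pd.DataFrame
    readings: pd.DataFrame
    scales: dict[str, ScoreScale] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        exams, readings = self.exams, self.readings
        for col in _EXAM_REQUIRED:
            if col not in exams.columns:
                raise FormatError(f"exam table missing column {col!r}")
        for col in ("ai_category", "raw_score"):
            if col not in exams.columns:
                exams[col] = np.nan
        for col in _READING_REQUIRED:
            if col not in readings.columns:
                raise FormatError(f"reading table missing column {col!r}")

        bad_truth = exams.loc[~exams["truth"].isin(TRUTH_LABELS)]
        if len(bad_truth):
            raise ValidationError(
                f"unknown truth labels in rows {bad_truth.index.tolist()[:10]}"
            )
        dup = exams["exam_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate exam_id values: {exams.loc[dup, 'exam_id'].tolist()[:10]}"
            )

        cat = exams["ai_category"]
        has_cat = cat.notna()
        bad_cat = exams.loc[has_cat & ~cat.isin(range(1, 11))]
        if len(bad_cat):
            raise ValidationError(
                "ai_category outside [1, 10] for exams "
                f"{bad_cat['exam_id'].tolist()[:10]}"
            )
        orphan_score = exams.loc[~has_cat & exams["raw_score"].isna()]
        if len(orphan_score):
            raise ValidationError(
                "exams with neither ai_category nor raw_score: "
                f"{orphan_score['exam_id'].tolist()[:10]}"
            )

        if len(readings):
            dup = readings.duplicated(subset=["exam_id", "reader_id"])
            if dup.any():
                raise ValidationError(
                    "duplicate (exam_id, reader_id) pairs in rows "
                    f"{readings.index[dup].tolist()[:10]}"
                )
            known = set(exams["exam_id"])
            unknown = readings.loc[~readings["exam_id"].isin(known)]
            if len(unknown):
                raise IntegrityError(
                    "readings reference unknown exams: "
                    f"{unknown['exam_id'].tolist()[:10]}"
                )
            bad_scale = readings.loc[readings["scale_min"] >= readings["scale_max"]]
            if len(bad_scale):
                raise ValidationError(
                    f"scale_min >= scale_max in rows {bad_scale.index.tolist()[:10]}"
                )
            out = readings.loc[
                (readings["score"] < readings["scale_min"])
                | (readings["score"] > readings["scale_max"])
            ]
            if len(out):
                raise ValidationError(
                    f"scores outside their declared scale in rows "
                    f"{out.index.tolist()[:10]}"
                )
            for mn, mx in (
                readings[["scale_min", "scale_max"]].drop_duplicates().itertuples(index=False)
            ):
                scale = ScoreScale.from_bounds(mn, mx)
                self.scales.setdefault(scale.scale_id, scale)

    # -- summaries --------------------------------------------------------

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.exams["truth"].value_counts()
        return {label: int(counts.get(label, 0)) for label in TRUTH_LABELS}

    @property
    def n_exams(self) -> int:
        return len(self.exams)

    @property
    def n_readings(self) -> int:
        return len(self.readings)

    def incidence_matrix(self) -> pd.DataFrame:
        """Reader-by-exam 0/1 incidence matrix of the realized design."""
        if not len(self.readings):
            return pd.DataFrame(index=pd.Index([], name="reader_id"))
        mat = pd.crosstab(self.readings["reader_id"], self.readings["exam_id"])
        return (mat > 0).astype(int)


def load_dataset(exam_path: str | Path, reading_path: str | Path) -> ReadingDataset:
    """Read and validate an exam table and a reading table from CSV files."""
    exam_path, reading_path = Path(exam_path), Path(reading_path)
    for path in (exam_path, reading_path):
        if not path.exists():
            raise FormatError(f"input file not found: {path}")
    exams = pd.read_csv(exam_path, dtype={"exam_id": str, "study_id": str})
    try:
        readings = pd.read_csv(
            reading_path, dtype={"exam_id": str, "reader_id": str, "study_id": str}
        )
    except pd.errors.EmptyDataError:
        readings = pd.DataFrame(columns=list(READING_COLUMNS))
    missing = [c for c in _EXAM_REQUIRED if c not in exams.columns]
    missing += [c for c in _READING_REQUIRED if c not in readings.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    return ReadingDataset(exams=exams, readings=readings)


def write_dataset(ds: ReadingDataset, exam_path: str | Path, reading_path: str | Path) -> None:
    """Write a dataset back to the two-file CSV contract."""
    ds.exams.loc[:, list(EXAM_COLUMNS)].to_csv(exam_path, index=False)
    ds.readings.loc[:, list(READING_COLUMNS)].to_csv(reading_path, index=False)


def design_summary(ds: ReadingDataset) -> pd.DataFrame:
    """Per-block design report: readers, cases per class, crossing completeness.

    A block is *fully crossed* when every reader appearing in the block read
    every exam of the block.
    """
    rows = []
    exam_truth = ds.exams.set_index("exam_id")["truth"]
    readings_by_block: Mapping[str, pd.DataFrame]
    if len(ds.readings):
        readings_by_block = dict(tuple(ds.readings.groupby("study_id")))
    else:
        readings_by_block = {}
    for study_id, block_exams in ds.exams.groupby("study_id"):
        block_readings = readings_by_block.get(study_id)
        counts = block_exams["truth"].value_counts()
        n_exams = len(block_exams)
        if block_readings is None or not len(block_readings):
            n_readers, n_readings, crossed = 0, 0, False
        else:
            n_readers = block_readings["reader_id"].nunique()
            n_readings = len(block_readings)
            inc = pd.crosstab(block_readings["reader_id"], block_readings["exam_id"])
            crossed = (
                inc.shape[1] == n_exams
                and bool((inc.to_numpy() > 0).all())
            )
        rows.append(
            {
                "study_id": study_id,
                "n_readers": n_readers,
                "n_exams": n_exams,
                "n_cancer": int(counts.get("cancer", 0)),
                "n_benign": int(counts.get("benign", 0)),
                "n_normal": int(counts.get("normal", 0)),
                "n_readings": n_readings,
                "fully_crossed": crossed,
            }
        )
    return pd.DataFrame(rows)


def dataset_from_records(
    exams: Iterable[ExamRecord],
    readings: Iterable[ReadingRecord],
    scales: Iterable[ScoreScale],
) -> ReadingDataset:
    """Assemble a dataset from typed record objects (mainly for tests)."""
    scale_map = {s.scale_id: s for s in scales}
    exam_rows = [
        {
            "exam_id": e.exam_id,
            "study_id": e.study_id,
            "truth": e.truth,
            "ai_category": e.ai_category,
            "raw_score": e.raw_score,
        }
        for e in exams
    ]
    reading_rows = []
    for r in readings:
        if r.scale_id not in scale_map:
            raise IntegrityError(f"reading references unknown scale {r.scale_id!r}")
        scale = scale_map[r.scale_id]
        reading_rows.append(
            {
                "exam_id": r.exam_id,
                "reader_id": r.reader_id,
                "study_id": r.study_id,
                "score": r.score,
                "scale_min": scale.minimum,
                "scale_max": scale.maximum,
            }
        )
    return ReadingDataset(
        exams=pd.DataFrame(exam_rows, columns=list(EXAM_COLUMNS)),
        readings=pd.DataFrame(reading_rows, columns=list(READING_COLUMNS)),
    )
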