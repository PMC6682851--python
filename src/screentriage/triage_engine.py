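"""AI-score calibration, threshold triage and radiologist-score reassignment.

Triage semantics: at threshold ``t`` (an integer 1-9) an exam is *excluded*
from human reading iff its AI category is ``<= t``; the remaining exams are
*pre-selected* for evaluation.  Excluded exams are automatically reported as
normal, which is modelled downstream by reassigning every radiologist score
of an excluded exam to the minimum of its scale.

Two workload figures are emitted per threshold:

``workload_reduction_screening``
    excluded fraction of the *normal* exams — the operative quantity for a
    screening population, which is dominated by normals;
``workload_reduction_sample``
    excluded fraction of all exams in the (enriched) analyzed sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, IntegrityError, ValidationError
from .reading_data import ReadingDataset, TRUTH_LABELS

N_CATEGORIES = 10


@dataclass(frozen=True)
class CalibrationMap:
    """Decile map from a continuous suspicion score to categories 1-10.

    ``cutpoints`` are the nine 10%..90% empirical quantiles (type-1 /
    inverse-CDF) of the calibration normals; category ``k`` covers the
    half-open interval ``(cutpoints[k-2], cutpoints[k-1]]`` with the two
    outer categories unbounded.
    """

    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutpoints) != N_CATEGORIES - 1:
            raise CalibrationError(f"expected 9 cutpoints, got {len(self.cutpoints)}")
        diffs = np.diff(self.cutpoints)
        if not (diffs > 0).all():
            raise CalibrationError("cutpoints must be strictly ascending")

    def apply(self, scores: Iterable[float]) -> np.ndarray:
        """Map raw scores to integer categories 1-10 (boundary -> lower)."""
        scores = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores)
        return np.searchsorted(np.asarray(self.cutpoints), scores, side="left") + 1


def calibrate(raw_scores_of_normals: Iterable[float]) -> CalibrationMap:
    """Fit a decile calibration on the raw scores of normal exams.

    Each category then holds approximately 10% of the calibration normals
    (exactly n/10 when n is a multiple of 10 and scores are distinct).
    """
    scores = np.asarray(list(raw_scores_of_normals), dtype=float)
    if scores.size < N_CATEGORIES:
        raise CalibrationError(f"need at least {N_CATEGORIES} scores, got {scores.size}")
    cuts = np.quantile(scores, np.arange(1, N_CATEGORIES) / N_CATEGORIES, method="inverted_cdf")
    if not (np.diff(cuts) > 0).all():
        raise CalibrationError("degenerate score sample: decile cutpoints are not distinct")
    return CalibrationMap(tuple(float(c) for c in cuts))


@dataclass(frozen=True)
class TriageResult:
    """Partition of the exams at one threshold, with exclusion statistics."""

    threshold: int
    excluded_exam_ids: tuple[str, ...]
    preselected_exam_ids: tuple[str, ...]
    excl_fraction_by_class: dict[str, float]
    workload_reduction_screening: float
    workload_reduction_sample: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_exam_ids)


def _exam_table(exams: ReadingDataset | pd.DataFrame) -> pd.DataFrame:
    return exams.exams if isinstance(exams, ReadingDataset) else exams


def partition(exams: ReadingDataset | pd.DataFrame, threshold: int) -> TriageResult:
    """Split exams into excluded (``ai_category <= threshold``) and pre-selected."""
    if not 1 <= int(threshold) <= 9 or int(threshold) != threshold:
        raise ValidationError(f"threshold must be an integer in [1, 9], got {threshold}")
    threshold = int(threshold)
    table = _exam_table(exams)
    if table["ai_category"].isna().any():
        missing = table.loc[table["ai_category"].isna(), "exam_id"].tolist()[:10]
        raise ValidationError(f"exams without ai_category cannot be triaged: {missing}")
    cat = table["ai_category"].to_numpy(dtype=int)
    excluded_mask = cat <= threshold
    fractions = {}
    for label in TRUTH_LABELS:
        in_class = (table["truth"] == label).to_numpy()
        fractions[label] = (
            float(excluded_mask[in_class].mean()) if in_class.any() else 0.0
        )
    return TriageResult(
        threshold=threshold,
        excluded_exam_ids=tuple(table.loc[excluded_mask, "exam_id"]),
        preselected_exam_ids=tuple(table.loc[~excluded_mask, "exam_id"]),
        excl_fraction_by_class=fractions,
        workload_reduction_screening=fractions["normal"],
        workload_reduction_sample=float(excluded_mask.mean()) if len(table) else 0.0,
    )


def reassign_scores(ds: ReadingDataset, excluded_exam_ids: Iterable[str]) -> pd.DataFrame:
    """Reassign all readings of excluded exams to their scale's minimum.

    Readings of pre-selected exams are returned bit-identical (the
    invariance-of-reader-behaviour assumption).
    """
    excluded = set(excluded_exam_ids)
    unknown = excluded - set(ds.exams["exam_id"])
    if unknown:
        raise IntegrityError(f"unknown excluded exam ids: {sorted(unknown)[:10]}")
    readings = ds.readings.copy()
    if len(readings):
        mask = readings["exam_id"].isin(excluded)
        readings.loc[mask, "score"] = readings.loc[mask, "scale_min"]
    return readings


def sweep(exams: ReadingDataset | pd.DataFrame) -> list[TriageResult]:
    """Triage results for every threshold 1..9 (exclusion is monotone in t)."""
    return [partition(exams, t) for t in range(1, 10)]


def sweep_table(results: Sequence[TriageResult]) -> pd.DataFrame:
    """Flatten sweep results to the ``tradeoff.csv`` column contract.

    ``pct_*`` columns are percentages (0-100); the two workload-reduction
    columns are fractions (0-1).
    """
    return pd.DataFrame(
        {
            "threshold": [r.threshold for r in results],
            "n_excluded": [r.n_excluded for r in results],
            "pct_normal_excluded": [100 * r.excl_fraction_by_class["normal"] for r in results],
            "pct_benign_excluded": [100 * r.excl_fraction_by_class["benign"] for r in results],
            "pct_cancer_excluded": [100 * r.excl_fraction_by_class["cancer"] for r in results],
            "workload_reduction_screening": [r.workload_reduction_screening for r in results],
            "workload_reduction_sample": [r.workload_reduction_sample for r in results],
        }
    )


def category_summary(exams: ReadingDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-class percentage of exams in each AI category (distribution check)."""
    table = _exam_table(exams)
    rows = []
    for label in TRUTH_LABELS:
        sub = table.loc[table["truth"] == label, "ai_category"]
        n = len(sub)
        counts = sub.value_counts()
        for c in range(1, N_CATEGORIES + 1):
            rows.append(
                {
                    "truth": label,
                    "ai_category": c,
                    "n": int(counts.get(c, 0)),
                    "pct": 100.0 * counts.get(c, 0) / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
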