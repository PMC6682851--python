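import numpy as np
import pandas as pd
import pytest

from screentriage.reading_data import ReadingDataset
from screentriage.synthetic_cohort import fixture_config, generate_split_plot


@pytest.fixture(scope="session")
def fixture_dataset() -> ReadingDataset:
    """The 2654-exam, 9-block synthetic fixture cohort (seed 7)."""
    return generate_split_plot(fixture_config(seed=7))


def make_dataset(
    truths,
    categories,
    scores_by_reader,
    study_ids=None,
    scale=(1.0, 10.0),
) -> ReadingDataset:
    """Hand-rolled tiny dataset: one score list per reader over all exams."""
    n = len(truths)
    exam_ids = [f"E{i:03d}" for i in range(n)]
    if study_ids is None:
        study_ids = ["B1"] * n
    exams = pd.DataFrame(
        {
            "exam_id": exam_ids,
            "study_id": study_ids,
            "truth": truths,
            "ai_category": categories,
            "raw_score": np.nan,
        }
    )
    rows = []
    for reader_id, scores in scores_by_reader.items():
        for exam_id, study_id, score in zip(exam_ids, study_ids, scores):
            rows.append(
                {
                    "exam_id": exam_id,
                    "reader_id": reader_id,
                    "study_id": study_id,
                    "score": float(score),
                    "scale_min": scale[0],
                    "scale_max": scale[1],
                }
            )
    readings = pd.DataFrame(
        rows,
        columns=["exam_id", "reader_id", "study_id", "score", "scale_min", "scale_max"],
    )
    return ReadingDataset(exams=exams, readings=readings)


def brute_force_auc(pos, neg) -> float:
    """Independent Mann-Whitney oracle: explicit loop over all pairs."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
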