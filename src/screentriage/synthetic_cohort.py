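"""Seeded generator of exams and multi-reader malignancy scores.

Produces split-plot reading datasets — several disjoint study blocks, each
with its own readers and exams and fully crossed within the block — with the
statistical structure the downstream triage and MRMC stages assume:

* per-truth-class AI-category distributions with known marginals,
* reader scores drawn from a Gaussian latent model whose latent suspicion is
  coupled to the AI category (``lambda_ai``), so exams the AI puts in low
  categories also tend to receive low reader scores.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; draws happen in a fixed documented order (blocks ascending; per
block: exam latent effects in exam order, then reader noise reader-major),
so a seed fully determines the output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError
from .reading_data import ReadingDataset, ScoreScale

N_CATEGORIES = 10

# Default per-class AI-category distributions (categories 1..10).  Pinned
# marginals: cancer category 10 = 72.5%, cancer categories 5-10 = 95.1%,
# benign category 10 = 27%, normal mean per category = 10%; cumulative
# exclusion masses at thresholds 2 and 5 are 17%/47% (normal), 1%/7%
# (cancer) and 5%/27% (benign).  The split inside those constraints is a
# modelling choice.
_DEFAULT_NORMAL = (0.080, 0.090, 0.100, 0.100, 0.100, 0.106, 0.106, 0.106, 0.106, 0.106)
_DEFAULT_CANCER = (0.004, 0.006, 0.017, 0.022, 0.021, 0.030, 0.045, 0.055, 0.075, 0.725)
_DEFAULT_BENIGN = (0.020, 0.030, 0.060, 0.080, 0.080, 0.100, 0.110, 0.120, 0.130, 0.270)

# Class composition of the 2654-exam fixture cohort.
FIXTURE_COUNTS = {"cancer": 653, "benign": 768, "normal": 1233}


@dataclass(frozen=True)
class CategoryDistribution:
    """A probability distribution over the 10 AI score categories."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != N_CATEGORIES:
            raise ConfigError(f"expected {N_CATEGORIES} proportions, got {len(self.probs)}")
        if any(p < 0 for p in self.probs):
            raise ConfigError("category proportions must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError(f"category proportions sum to {sum(self.probs)}, not 1")

    def mass(self, categories: range | tuple[int, ...]) -> float:
        """Total probability of the given categories (1-based)."""
        return float(sum(self.probs[c - 1] for c in categories))


class DefaultDistributions(NamedTuple):
    normal: CategoryDistribution
    cancer: CategoryDistribution
    benign: CategoryDistribution


def default_distributions() -> DefaultDistributions:
    """The default normal / cancer / benign AI-category distributions."""
    return DefaultDistributions(
        normal=CategoryDistribution(_DEFAULT_NORMAL),
        cancer=CategoryDistribution(_DEFAULT_CANCER),
        benign=CategoryDistribution(_DEFAULT_BENIGN),
    )


@dataclass(frozen=True)
class ReaderModel:
    """Gaussian latent model for radiologist malignancy scores.

    A reader's score for an exam is ``clip(latent + reader noise)`` where

    ``latent = mu_class + lambda_ai * (ai_category - 5.5) / 4.5 + exam effect``

    with ``mu_class`` equal to ``mu_pos`` for cancer exams and ``mu_neg``
    otherwise, the exam effect ~ N(0, sigma_exam^2), and reader noise
    ~ N(0, sigma_reader^2).  ``lambda_ai > 0`` couples reader suspicion to
    the AI category so low-category cancers also tend to be scored low.
    """

    n_studies: int = 9
    readers_per_study: int = 4
    mu_pos: float = 5.2
    mu_neg: float = 4.5
    sigma_exam: float = 0.7
    sigma_reader: float = 0.7
    lambda_ai: float = 4.5
    scale: ScoreScale = field(default_factory=lambda: ScoreScale("los-1-10", 1.0, 10.0))

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.readers_per_study < 1:
            raise ConfigError("n_studies and readers_per_study must be >= 1")
        if self.sigma_exam <= 0 or self.sigma_reader < 0:
            raise ConfigError("sigma_exam must be > 0 and sigma_reader >= 0")
        if not self.mu_pos > self.mu_neg:
            raise ConfigError("mu_pos must exceed mu_neg")
        if self.lambda_ai < 0:
            raise ConfigError("lambda_ai must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic split-plot cohort."""

    n_normal: int
    n_benign: int
    n_cancer: int
    distributions: DefaultDistributions = field(default_factory=default_distributions)
    reader_model: ReaderModel = field(default_factory=ReaderModel)
    exact_proportions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_benign", "n_cancer"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def fixture_config(seed: int = 0, **overrides) -> CohortConfig:
    """The 2654-exam fixture cohort (653 cancer / 768 benign / 1233 normal)."""
    cfg = CohortConfig(
        n_normal=FIXTURE_COUNTS["normal"],
        n_benign=FIXTURE_COUNTS["benign"],
        n_cancer=FIXTURE_COUNTS["cancer"],
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def largest_remainder(n: int, probs: tuple[float, ...] | np.ndarray) -> np.ndarray:
    """Apportion ``n`` items to categories by the largest-remainder method.

    Deterministic: remainder ties are broken in favour of lower category
    indices.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    quotas = n * np.asarray(probs, dtype=float)
    counts = np.floor(quotas).astype(int)
    shortfall = n - int(counts.sum())
    if shortfall:
        remainders = quotas - counts
        # stable sort on -remainder keeps lower indices first among ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:shortfall]] += 1
    return counts


def generate_exams(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the exam table: class, AI category, block assignment.

    With ``exact_proportions`` the per-class category counts are the
    largest-remainder apportionment of ``n * probs`` (deterministic);
    otherwise categories are i.i.d. draws from the class distribution.
    Exams of each class are dealt round-robin over the study blocks, and the
    drawn categories are randomly permuted within the class so category and
    block are decoupled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dists = config.distributions
    n_by_class = {
        "normal": config.n_normal,
        "cancer": config.n_cancer,
        "benign": config.n_benign,
    }
    n_studies = config.reader_model.n_studies
    rows: list[dict] = []
    serial = 0
    for truth in ("normal", "benign", "cancer"):
        n = n_by_class[truth]
        probs = getattr(dists, truth).probs
        if config.exact_proportions:
            counts = largest_remainder(n, probs)
            cats = np.repeat(np.arange(1, N_CATEGORIES + 1), counts)
        else:
            cats = rng.choice(np.arange(1, N_CATEGORIES + 1), size=n, p=probs)
        cats = rng.permutation(cats)
        for k in range(n):
            serial += 1
            rows.append(
                {
                    "exam_id": f"E{serial:06d}",
                    "study_id": f"B{k % n_studies + 1:02d}",
                    "truth": truth,
                    "ai_category": int(cats[k]),
                    "raw_score": np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["exam_id", "study_id", "truth", "ai_category", "raw_score"]
    )


def generate_readings(
    exams: pd.DataFrame,
    model: ReaderModel,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the reading table: every block reader scores every block exam."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if exams["study_id"].isna().any():
        raise GenerationError("every exam needs a study block assignment")
    scale = model.scale
    frames: list[pd.DataFrame] = []
    for study_id in sorted(exams["study_id"].unique()):
        block = exams.loc[exams["study_id"] == study_id]
        n_exams = len(block)
        mu = np.where(block["truth"].to_numpy() == "cancer", model.mu_pos, model.mu_neg)
        cat = block["ai_category"].to_numpy(dtype=float)
        latent = (
            mu
            + model.lambda_ai * (cat - 5.5) / 4.5
            + rng.normal(0.0, model.sigma_exam, size=n_exams)
        )
        noise = rng.normal(0.0, model.sigma_reader, size=(model.readers_per_study, n_exams))
        scores = np.clip(latent[None, :] + noise, scale.minimum, scale.maximum)
        for r in range(model.readers_per_study):
            frames.append(
                pd.DataFrame(
                    {
                        "exam_id": block["exam_id"].to_numpy(),
                        "reader_id": f"{study_id}R{r + 1:02d}",
                        "study_id": study_id,
                        "score": scores[r],
                        "scale_min": scale.minimum,
                        "scale_max": scale.maximum,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["exam_id", "reader_id", "study_id", "score", "scale_min", "scale_max"]
        )
    return pd.concat(frames, ignore_index=True)


def generate_split_plot(config: CohortConfig) -> ReadingDataset:
    """Generate a pooled split-plot dataset: exams plus crossed block readings."""
    rng = np.random.default_rng(config.seed)
    exams = generate_exams(config, rng)
    readings = generate_readings(exams, config.reader_model, rng)
    return ReadingDataset(exams=exams, readings=readings)
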