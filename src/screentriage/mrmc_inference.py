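"""Reader-averaged ROC analysis for arbitrary (e.g. split-plot) designs.

Provides per-reader nonparametric (trapezoidal) ROC curves and Mann-Whitney
AUCs, area-preserving averaging of reader curves along directions
perpendicular to the chance diagonal, an unbiased U-statistic variance
estimator for the reader-averaged AUC on the realized design, and
Bonferroni-corrected non-inferiority comparison of triage scenarios against
the original reading.

Variance estimator
------------------
Write the reader-averaged AUC as a weighted sum of success indicators
``psi(r, i, j)`` (1 / 0.5 / 0 for a positive case ``i`` scored above / equal
to / below a negative case ``j`` by reader ``r``) over the realized design,
with reader weights ``1 / (R * n1_r * n0_r)``.  Under the random-reader
random-case model the expectation of a product ``psi * psi'`` depends only
on the same/different pattern of the (reader, positive, negative) index
triples; pairs with all three indices different are independent, so their
product has expectation ``A^2``.  Hence

    var_hat = auc_hat**2 - C_hat

is unbiased for ``Var(auc_hat)``, where ``C_hat`` is a weighted average of
``psi * psi'`` over term pairs with different readers, different positive
cases and different negative cases.  With a single reader (or no such
pairs), same-reader pairs with both cases different are used instead, which
reduces to the classical fixed-reader unbiased AUC variance.  Unbiased
moment differences can come out negative; negative estimates are truncated
to zero with a warning.  The same decomposition applied to per-triple psi
*differences* between two scenarios read by identical readers on identical
cases yields the paired variance of the AUC difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import EstimationError, ValidationError
from .reading_data import ReadingDataset
from .triage_engine import TriageResult, partition, reassign_scores

_SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# per-reader ROC primitives
# ---------------------------------------------------------------------------


def trapezoidal_auc(pos_scores: Iterable[float], neg_scores: Iterable[float]) -> float:
    """Mann-Whitney AUC: mean of psi over all (positive, negative) pairs.

    psi is 1 when the positive scores above the negative, 0.5 on ties,
    0 otherwise; equals the area under the trapezoidal ROC curve.
    """
    pos = np.asarray(list(pos_scores) if not isinstance(pos_scores, np.ndarray) else pos_scores, dtype=float)
    neg = np.asarray(list(neg_scores) if not isinstance(neg_scores, np.ndarray) else neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EstimationError("AUC needs at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class ReaderCurve:
    """One reader's empirical (trapezoidal) ROC polyline and its area."""

    reader_id: str
    points: np.ndarray  # (k, 2) array of (FPF, TPF) vertices
    auc: float


@dataclass(frozen=True)
class AveragedCurve:
    """Reader-averaged ROC polyline; area equals the mean reader AUC."""

    points: np.ndarray
    auc: float


def reader_curve(
    pos_scores: Iterable[float],
    neg_scores: Iterable[float],
    reader_id: str = "",
) -> ReaderCurve:
    """Empirical ROC vertices from sweeping the threshold over distinct scores."""
    pos = np.asarray(list(pos_scores) if not isinstance(pos_scores, np.ndarray) else pos_scores, dtype=float)
    neg = np.asarray(list(neg_scores) if not isinstance(neg_scores, np.ndarray) else neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EstimationError(
            f"reader {reader_id!r} lacks a truth class; ROC curve undefined"
        )
    cuts = np.unique(np.concatenate([pos, neg]))[::-1]
    tpf = np.concatenate([[0.0], (pos[None, :] >= cuts[:, None]).mean(axis=1)])
    fpf = np.concatenate([[0.0], (neg[None, :] >= cuts[:, None]).mean(axis=1)])
    points = np.column_stack([fpf, tpf])
    auc = float(np.trapezoid(tpf, fpf))
    return ReaderCurve(reader_id=reader_id, points=points, auc=auc)


def _rotate(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map (FPF, TPF) to (u, v): u along the chance line, v perpendicular."""
    x, y = points[:, 0], points[:, 1]
    return (x + y) / _SQRT2, (y - x) / _SQRT2


def average_curves(curves: Sequence[ReaderCurve], grid_size: int = 1001) -> AveragedCurve:
    """Average reader ROC curves along lines perpendicular to the chance line.

    Each curve is rotated 45 degrees so the chance diagonal becomes the
    horizontal axis, interpolated on a common abscissa grid (a uniform grid
    of ``grid_size`` points augmented with every curve's own breakpoints, so
    piecewise-linear curves are represented exactly), averaged pointwise and
    rotated back.  The averaged curve's area equals the arithmetic mean of
    the input areas (area preservation).
    """
    if not curves:
        raise ValidationError("average_curves needs at least one curve")
    rotated = []
    for c in curves:
        u, v = _rotate(c.points)
        # collapse duplicated abscissae to their upper envelope
        order = np.argsort(u, kind="stable")
        u, v = u[order], v[order]
        uu, inverse = np.unique(u, return_inverse=True)
        vv = np.full(uu.shape, -np.inf)
        np.maximum.at(vv, inverse, v)
        rotated.append((uu, vv))
    grid = np.unique(
        np.concatenate([np.linspace(0.0, _SQRT2, grid_size)] + [u for u, _ in rotated])
    )
    mean_v = np.mean([np.interp(grid, u, v) for u, v in rotated], axis=0)
    x = (grid - mean_v) / _SQRT2
    y = (grid + mean_v) / _SQRT2
    points = np.column_stack([x, y])
    return AveragedCurve(points=points, auc=float(np.trapezoid(y, x)))


# ---------------------------------------------------------------------------
# U-statistic variance estimation on the realized design
# ---------------------------------------------------------------------------


@dataclass
class _ReaderBlock:
    """One reader's psi matrix over the (positive, negative) cases they read."""

    reader_id: str
    pos_ids: np.ndarray  # sorted exam ids (as object array) of positives read
    neg_ids: np.ndarray
    psi: np.ndarray  # (n_pos, n_neg)

    @property
    def n1(self) -> int:
        return len(self.pos_ids)

    @property
    def n0(self) -> int:
        return len(self.neg_ids)


def _psi_matrix(pos_scores: np.ndarray, neg_scores: np.ndarray) -> np.ndarray:
    diff = pos_scores[:, None] - neg_scores[None, :]
    return (diff > 0).astype(float) + 0.5 * (diff == 0)


def _reader_blocks(ds: ReadingDataset, readings: pd.DataFrame) -> list[_ReaderBlock]:
    """Split a reading table into per-reader psi blocks; drop one-class readers."""
    truth = ds.exams.set_index("exam_id")["truth"]
    is_pos = truth == "cancer"
    blocks: list[_ReaderBlock] = []
    dropped: list[str] = []
    for reader_id, sub in readings.groupby("reader_id", sort=True):
        sub = sub.sort_values("exam_id")
        pos_mask = is_pos.loc[sub["exam_id"]].to_numpy()
        pos = sub.loc[pos_mask]
        neg = sub.loc[~pos_mask]
        if not len(pos) or not len(neg):
            dropped.append(str(reader_id))
            continue
        blocks.append(
            _ReaderBlock(
                reader_id=str(reader_id),
                pos_ids=pos["exam_id"].to_numpy(),
                neg_ids=neg["exam_id"].to_numpy(),
                psi=_psi_matrix(pos["score"].to_numpy(float), neg["score"].to_numpy(float)),
            )
        )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} reader(s) without both truth classes: "
            f"{dropped[:5]}",
            stacklevel=3,
        )
    if not blocks:
        raise EstimationError("no reader has both a positive and a negative exam")
    return blocks


def _ustat_mean_var(blocks: Sequence[_ReaderBlock]) -> tuple[float, float]:
    """Reader-averaged mean of psi and unbiased variance of that average."""
    R = len(blocks)
    weights = np.array([1.0 / (R * b.n1 * b.n0) for b in blocks])
    totals = np.array([b.psi.sum() for b in blocks])
    # mean-of-means keeps degenerate cases (all psi = 0.5) exact
    auc_hat = float(np.mean([t / (b.n1 * b.n0) for t, b in zip(totals, blocks)]))

    row_sums = [b.psi.sum(axis=1) for b in blocks]  # per positive case
    col_sums = [b.psi.sum(axis=0) for b in blocks]  # per negative case

    num = 0.0
    den = 0.0
    for a in range(R):
        for b in range(a + 1, R):
            A, B = blocks[a], blocks[b]
            cp_a, cp_b = _intersect_indices(A.pos_ids, B.pos_ids)
            cn_a, cn_b = _intersect_indices(A.neg_ids, B.neg_ids)
            s = totals[a] * totals[b]
            s -= float(np.dot(row_sums[a][cp_a], row_sums[b][cp_b]))
            s -= float(np.dot(col_sums[a][cn_a], col_sums[b][cn_b]))
            s += float(np.sum(A.psi[np.ix_(cp_a, cn_a)] * B.psi[np.ix_(cp_b, cn_b)]))
            count = (A.n1 * B.n1 - len(cp_a)) * (A.n0 * B.n0 - len(cn_a))
            w = 2.0 * weights[a] * weights[b]
            num += w * s
            den += w * count
    if den <= 0:
        # single reader (or no cross-reader pairs with all-distinct cases):
        # fall back to same-reader pairs with both cases different
        for a in range(R):
            A = blocks[a]
            s = totals[a] ** 2
            s -= float(np.sum(row_sums[a] ** 2))
            s -= float(np.sum(col_sums[a] ** 2))
            s += float(np.sum(A.psi**2))
            count = A.n1 * (A.n1 - 1) * A.n0 * (A.n0 - 1)
            num += weights[a] ** 2 * s
            den += weights[a] ** 2 * count
    if den <= 0:
        raise EstimationError(
            "design too small to estimate the AUC variance (need >= 2 cases per class)"
        )
    var_raw = auc_hat**2 - num / den
    if var_raw < 0:
        if var_raw < -1e-12:
            warnings.warn(
                f"negative variance estimate ({var_raw:.3e}) truncated to 0",
                stacklevel=3,
            )
        var_raw = 0.0
    return auc_hat, var_raw


def _intersect_indices(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, ia, ib = np.intersect1d(a, b, assume_unique=True, return_indices=True)
    return ia, ib


def _diff_blocks(
    scenario: Sequence[_ReaderBlock], baseline: Sequence[_ReaderBlock]
) -> list[_ReaderBlock]:
    by_id = {b.reader_id: b for b in baseline}
    if set(by_id) != {b.reader_id for b in scenario}:
        raise EstimationError("paired comparison requires identical reader sets")
    out = []
    for s in scenario:
        b = by_id[s.reader_id]
        if not (np.array_equal(s.pos_ids, b.pos_ids) and np.array_equal(s.neg_ids, b.neg_ids)):
            raise EstimationError(
                f"paired comparison requires identical cases per reader "
                f"(mismatch for reader {s.reader_id!r})"
            )
        out.append(
            _ReaderBlock(
                reader_id=s.reader_id,
                pos_ids=s.pos_ids,
                neg_ids=s.neg_ids,
                psi=s.psi - b.psi,
            )
        )
    return out


@dataclass
class MRMCResult:
    """Reader-averaged AUC (and optionally a paired scenario comparison)."""

    scenario: str
    auc_hat: float
    var_hat: float
    threshold: int | None = None
    delta: float | None = None
    var_delta: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    noninferior: bool | None = None
    margin: float | None = None


def mrmc_variance(
    ds: ReadingDataset,
    readings: pd.DataFrame | None = None,
    baseline_readings: pd.DataFrame | None = None,
    scenario: str = "scenario",
) -> MRMCResult:
    """Reader-averaged AUC with an unbiased variance on the realized design.

    ``readings`` defaults to ``ds.readings``.  When ``baseline_readings`` is
    supplied (same readers and cases), the paired difference
    ``auc(readings) - auc(baseline)`` and its variance are also estimated,
    by applying the same moment decomposition to per-triple psi differences.
    """
    if readings is None:
        readings = ds.readings
    blocks = _reader_blocks(ds, readings)
    auc_hat, var_hat = _ustat_mean_var(blocks)
    result = MRMCResult(scenario=scenario, auc_hat=auc_hat, var_hat=var_hat)
    if baseline_readings is not None:
        base_blocks = _reader_blocks(ds, baseline_readings)
        diff = _diff_blocks(blocks, base_blocks)
        # psi differences live in [-1, 1]; the moment decomposition is the
        # same, the mean is now a difference of AUCs
        delta, var_delta = _ustat_mean_var(diff)
        result.delta = delta
        result.var_delta = var_delta
    return result


# ---------------------------------------------------------------------------
# non-inferiority testing and scenario comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NonInferiorityDecision:
    delta: float
    ci_low: float
    ci_high: float
    noninferior: bool
    margin: float
    level: float


def noninferiority_test(
    delta: float,
    var_delta: float,
    margin: float = 0.05,
    n_comparisons: int = 1,
    alpha: float = 0.05,
    require_positive_delta: bool = False,
) -> NonInferiorityDecision:
    """Bonferroni-adjusted normal-theory CI and non-inferiority decision.

    The two-sided CI is at level ``1 - alpha / n_comparisons``; the scenario
    is non-inferior when the CI lower bound exceeds ``-margin`` (optionally
    also requiring ``delta > 0``, off by default).
    """
    if var_delta < 0:
        raise ValidationError(f"var_delta must be >= 0, got {var_delta}")
    if margin <= 0 or n_comparisons < 1:
        raise ValidationError("margin must be > 0 and n_comparisons >= 1")
    level = 1.0 - alpha / n_comparisons
    z = norm.ppf(1.0 - alpha / (2.0 * n_comparisons))
    se = float(np.sqrt(var_delta))
    ci_low, ci_high = delta - z * se, delta + z * se
    noninferior = ci_low > -margin
    if require_positive_delta:
        noninferior = noninferior and delta > 0
    return NonInferiorityDecision(
        delta=delta, ci_low=ci_low, ci_high=ci_high,
        noninferior=noninferior, margin=margin, level=level,
    )


def compare_scenarios(
    ds: ReadingDataset,
    triage_results: Sequence[TriageResult] | None = None,
    margin: float = 0.05,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    grid_size: int = 1001,
) -> tuple[list[MRMCResult], dict[str, AveragedCurve]]:
    """Original vs. pre-selection reader-averaged AUC for every threshold.

    Returns one :class:`MRMCResult` for the original reading plus one per
    triage threshold (readings of excluded exams reassigned to scale
    minimum), with Bonferroni-corrected non-inferiority CIs on the paired
    AUC difference, and the area-preserving averaged ROC curve per scenario.
    """
    if triage_results is None:
        triage_results = [partition(ds, t) for t in range(1, 10)]
    if n_comparisons is None:
        n_comparisons = max(len(triage_results), 1)
    original = mrmc_variance(ds, scenario="original")
    results = [original]
    curves = {"original": _averaged_curve(ds, ds.readings, grid_size)}
    for tr in triage_results:
        label = f"threshold_{tr.threshold}"
        readings = reassign_scores(ds, tr.excluded_exam_ids)
        res = mrmc_variance(ds, readings, baseline_readings=ds.readings, scenario=label)
        res.threshold = tr.threshold
        decision = noninferiority_test(
            res.delta, res.var_delta, margin=margin,
            n_comparisons=n_comparisons, alpha=alpha,
        )
        res.ci_low, res.ci_high = decision.ci_low, decision.ci_high
        res.noninferior = decision.noninferior
        res.margin = margin
        results.append(res)
        curves[label] = _averaged_curve(ds, readings, grid_size)
    return results, curves


def _averaged_curve(
    ds: ReadingDataset, readings: pd.DataFrame, grid_size: int
) -> AveragedCurve:
    blocks = _reader_blocks(ds, readings)
    truth = ds.exams.set_index("exam_id")["truth"]
    reader_curves = []
    for b in blocks:
        sub = readings.loc[readings["reader_id"] == b.reader_id]
        pos_mask = (truth.loc[sub["exam_id"]] == "cancer").to_numpy()
        reader_curves.append(
            reader_curve(
                sub.loc[pos_mask, "score"].to_numpy(float),
                sub.loc[~pos_mask, "score"].to_numpy(float),
                b.reader_id,
            )
        )
    return average_curves(reader_curves, grid_size=grid_size)


def results_table(results: Sequence[MRMCResult]) -> pd.DataFrame:
    """Flatten scenario results to the ``mrmc.csv`` column contract."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "threshold": [r.threshold for r in results],
            "auc": [r.auc_hat for r in results],
            "var": [r.var_hat for r in results],
            "delta": [r.delta for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "noninferior": [r.noninferior for r in results],
        }
    )


def curves_table(curves: dict[str, AveragedCurve]) -> pd.DataFrame:
    """Flatten averaged curves to the ``roc_curves.csv`` column contract."""
    frames = []
    for scenario, curve in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "scenario": scenario,
                    "fpf": curve.points[:, 0],
                    "tpf": curve.points[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
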