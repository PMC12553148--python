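"""Participant-level train/test splitting and curve-level accuracy metrics.

Metrics are computed per test curve and aggregated per outcome as
mean (SD): RMSE in outcome units (square root of the mean squared
pointwise difference over the evaluation window), relRMSE as RMSE
normalised by the average of the observed and predicted curve ranges
(percent), and the Pearson correlation over the window. The evaluation
window defaults to the full 100-point cycle; a sub-window (e.g. stance
only) can be requested explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from gaitfosr.errors import (
    CovariateRangeError,
    DegenerateInputError,
    ValidationError,
)
from gaitfosr.inference import predict_mean
from gaitfosr.model import FOSRFit
from gaitfosr.records import CovariateRecord, GaitCurve


@dataclass(frozen=True)
class SplitAssignment:
    """Participant-level partition into training and test sets."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise ValidationError("train and test ids must be disjoint")


@dataclass
class CurveMetrics:
    """Accuracy of one predicted curve against its observation."""

    subject_id: str
    outcome: str
    rmse: float
    relrmse: float
    correlation: float | None  # None when either curve has zero variance


@dataclass
class OutcomeSummary:
    """Mean (SD) of each metric across the test curves of one outcome."""

    outcome: str
    n_curves: int
    rmse_mean: float
    rmse_sd: float
    relrmse_mean: float
    relrmse_sd: float
    correlation_mean: float | None
    correlation_sd: float | None
    n_excluded_correlation: int
    n_out_of_range: int = 0


@dataclass
class EvaluationReport:
    per_curve: dict[str, list[CurveMetrics]] = field(default_factory=dict)
    summaries: dict[str, OutcomeSummary] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for outcome, s in sorted(self.summaries.items()):
            rows.append(
                {
                    "outcome": outcome,
                    "n_curves": s.n_curves,
                    "rmse_mean": s.rmse_mean,
                    "rmse_sd": s.rmse_sd,
                    "relrmse_mean": s.relrmse_mean,
                    "relrmse_sd": s.relrmse_sd,
                    "correlation_mean": s.correlation_mean,
                    "correlation_sd": s.correlation_sd,
                    "n_excluded_correlation": s.n_excluded_correlation,
                    "n_out_of_range": s.n_out_of_range,
                }
            )
        return rows


def split_participants(
    ids: Sequence[str] | set[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitAssignment:
    """Random participant-level split; |train| = floor(fraction * |ids|)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    unique = sorted(set(ids))
    if len(unique) < 2:
        raise ValidationError("need at least 2 unique participant ids to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_train = int(np.floor(train_fraction * len(unique)))
    train = frozenset(unique[i] for i in order[:n_train])
    test = frozenset(unique[i] for i in order[n_train:])
    return SplitAssignment(
        train_ids=train, test_ids=test, seed=seed, train_fraction=train_fraction
    )


def _window_values(curve: GaitCurve, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return curve.values
    lo, hi = window
    if not (0 <= lo < hi <= curve.values.size):
        raise ValidationError(f"invalid evaluation window {window}")
    return curve.values[lo:hi]


def _check_pair(obs: GaitCurve, pred: GaitCurve) -> None:
    if obs.outcome != pred.outcome:
        raise ValidationError(
            f"outcome mismatch: {obs.outcome!r} vs {pred.outcome!r}"
        )
    if obs.values.size != pred.values.size:
        raise ValidationError("curves must share the same grid length")


def rmse_curve(
    obs: GaitCurve, pred: GaitCurve, window: tuple[int, int] | None = None
) -> float:
    """Root of the mean squared pointwise difference over the window."""
    _check_pair(obs, pred)
    a = _window_values(obs, window)
    b = _window_values(pred, window)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def relrmse_curve(
    obs: GaitCurve, pred: GaitCurve, window: tuple[int, int] | None = None
) -> float:
    """RMSE divided by the average of the two curve ranges, in percent."""
    _check_pair(obs, pred)
    a = _window_values(obs, window)
    b = _window_values(pred, window)
    denom = 0.5 * ((a.max() - a.min()) + (b.max() - b.min()))
    if denom == 0.0:
        raise DegenerateInputError(
            "both curves are constant over the window; relRMSE undefined"
        )
    return float(np.sqrt(np.mean((a - b) ** 2)) / denom * 100.0)


def pearson_curve(
    obs: GaitCurve, pred: GaitCurve, window: tuple[int, int] | None = None
) -> float | None:
    """Pearson correlation over the window; None if either curve is constant."""
    _check_pair(obs, pred)
    a = _window_values(obs, window)
    b = _window_values(pred, window)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _group_curves_by_outcome(
    curves: Sequence[GaitCurve], covariates: Sequence[CovariateRecord]
) -> dict[str, list[GaitCurve]]:
    groups: dict[str, list[GaitCurve]] = {}
    for curve in curves:
        groups.setdefault(curve.outcome, []).append(curve)
    for outcome, group in groups.items():
        if len(group) != len(covariates):
            raise ValidationError(
                f"outcome {outcome!r} has {len(group)} curves for "
                f"{len(covariates)} covariate records"
            )
        for curve, rec in zip(group, covariates):
            if curve.subject_id != rec.subject_id:
                raise ValidationError(
                    f"curve/covariate subject mismatch in outcome {outcome!r}: "
                    f"{curve.subject_id!r} vs {rec.subject_id!r}"
                )
    return groups


def _summarise(
    outcome: str, metrics: list[CurveMetrics]
) -> OutcomeSummary:
    rmses = np.array([m.rmse for m in metrics])
    rels = np.array([m.relrmse for m in metrics])
    cors = np.array([m.correlation for m in metrics if m.correlation is not None])
    n_excluded = len(metrics) - cors.size
    if n_excluded:
        warnings.warn(
            f"{n_excluded} curve(s) with undefined correlation excluded from "
            f"aggregation for outcome {outcome!r}",
            stacklevel=3,
        )
    return OutcomeSummary(
        outcome=outcome,
        n_curves=len(metrics),
        rmse_mean=float(rmses.mean()),
        rmse_sd=float(rmses.std(ddof=1)) if rmses.size > 1 else 0.0,
        relrmse_mean=float(rels.mean()),
        relrmse_sd=float(rels.std(ddof=1)) if rels.size > 1 else 0.0,
        correlation_mean=float(cors.mean()) if cors.size else None,
        correlation_sd=(
            float(cors.std(ddof=1)) if cors.size > 1 else (0.0 if cors.size else None)
        ),
        n_excluded_correlation=n_excluded,
    )


def evaluate_model(
    fits: FOSRFit | Mapping[str, FOSRFit],
    test_curves: Sequence[GaitCurve],
    test_covariates: Sequence[CovariateRecord],
    window: tuple[int, int] | None = None,
    allow_subject_overlap: bool = False,
) -> EvaluationReport:
    """Predict every test curve at the population level (random curve set
    to zero) and aggregate the three metrics per outcome as mean (SD).
    """
    fit_map: Mapping[str, FOSRFit]
    if isinstance(fits, FOSRFit):
        fit_map = {fits.outcome: fits}
    else:
        fit_map = fits
    groups = _group_curves_by_outcome(test_curves, test_covariates)
    test_subjects = {rec.subject_id for rec in test_covariates}
    report = EvaluationReport()
    for outcome, fit in fit_map.items():
        if outcome not in groups:
            raise ValidationError(f"no test curves for outcome {outcome!r}")
        overlap = test_subjects & set(fit.training_subjects)
        if overlap and not allow_subject_overlap:
            detail = (
                "deployment fit evaluated on its own training subjects"
                if fit.deployment
                else "test subjects overlap the fit's training subjects"
            )
            raise ValidationError(
                f"{detail}: {sorted(overlap)[:5]}...; pass "
                "allow_subject_overlap=True to override"
            )
        metrics: list[CurveMetrics] = []
        n_out_of_range = 0
        for curve, rec in zip(groups[outcome], test_covariates):
            try:
                predicted = predict_mean(fit, rec)
            except CovariateRangeError:
                # test profile outside the training covariate domain:
                # extrapolation is refused, so the curve is excluded
                n_out_of_range += 1
                continue
            pred_curve = GaitCurve(
                subject_id=rec.subject_id, outcome=outcome, values=predicted.mean
            )
            metrics.append(
                CurveMetrics(
                    subject_id=rec.subject_id,
                    outcome=outcome,
                    rmse=rmse_curve(curve, pred_curve, window),
                    relrmse=relrmse_curve(curve, pred_curve, window),
                    correlation=pearson_curve(curve, pred_curve, window),
                )
            )
        if not metrics:
            raise ValidationError(
                f"all test curves for outcome {outcome!r} fall outside the "
                "training covariate ranges"
            )
        if n_out_of_range:
            warnings.warn(
                f"{n_out_of_range} test curve(s) outside the training "
                f"covariate ranges excluded for outcome {outcome!r}",
                stacklevel=2,
            )
        report.per_curve[outcome] = metrics
        summary = _summarise(outcome, metrics)
        summary.n_out_of_range = n_out_of_range
        report.summaries[outcome] = summary
    return report
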