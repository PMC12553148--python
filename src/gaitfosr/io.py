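"""File formats: long-format waveform CSV, covariate CSV, fitted-model
bundles, prediction and report exports.

CSV dialect: UTF-8, comma-separated, '.' decimal, header mandatory.
Waveform CSV columns: subject_id, outcome, side, speed_condition, t, value
(one row per grid point; t must cover 0..99 exactly once per curve).
Covariate CSV: one row per observation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gaitfosr.errors import ValidationError
from gaitfosr.model import FOSRFit, ModelConfig
from gaitfosr.outcomes import N_GAIT_POINTS, OUTCOMES
from gaitfosr.records import CovariateRecord, GaitCurve
from gaitfosr.evaluation import EvaluationReport
from gaitfosr.inference import PredictedCurve, SmoothEffect

FIT_BUNDLE_VERSION = 1
_FLOAT_FORMAT = "%.17g"  # full double round-trip precision

CURVE_COLUMNS = ["subject_id", "outcome", "side", "speed_condition", "t", "value"]
COVARIATE_COLUMNS = [
    "subject_id", "sex", "age", "speed", "mass", "height", "cadence",
    "side", "speed_condition",
]


def write_curves(
    curves: Sequence[GaitCurve], path: str | Path
) -> None:
    """Write curves to the long-format waveform CSV."""
    rows = []
    for curve in curves:
        for t, value in zip(curve.t_grid.astype(int), curve.values):
            rows.append(
                (
                    curve.subject_id,
                    curve.outcome,
                    curve.side or "",
                    curve.speed_condition or "",
                    int(t),
                    value,
                )
            )
    frame = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_curves(path: str | Path) -> list[GaitCurve]:
    """Read and validate the long-format waveform CSV."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"waveform CSV missing columns {missing}")
    bad_outcomes = set(frame["outcome"]) - set(OUTCOMES)
    if bad_outcomes:
        row = int(frame.index[frame["outcome"].isin(bad_outcomes)][0]) + 2
        raise ValidationError(
            f"unknown outcome {sorted(bad_outcomes)[0]!r} at row {row}"
        )
    values = pd.to_numeric(frame["value"], errors="coerce")
    if values.isna().any():
        row = int(frame.index[values.isna()][0]) + 2
        raise ValidationError(f"non-numeric value at row {row}")
    frame["value"] = values
    curves = []
    keys = ["subject_id", "outcome", "side", "speed_condition"]
    frame["side"] = frame["side"].fillna("")
    frame["speed_condition"] = frame["speed_condition"].fillna("")
    for key, group in frame.groupby(keys, sort=False):
        t_values = group["t"].to_numpy()
        expected = np.arange(N_GAIT_POINTS)
        present = set(t_values.tolist())
        if len(t_values) != N_GAIT_POINTS or present != set(range(N_GAIT_POINTS)):
            missing_t = sorted(set(range(N_GAIT_POINTS)) - present)
            dupes = len(t_values) - len(present)
            detail = f"missing t={missing_t[:5]}" if missing_t else f"{dupes} duplicate t"
            raise ValidationError(
                f"curve {key} does not cover t=0..99 exactly once ({detail})"
            )
        ordered = group.sort_values("t")
        curves.append(
            GaitCurve(
                subject_id=str(key[0]),
                outcome=str(key[1]),
                values=ordered["value"].to_numpy(),
                side=str(key[2]) or None,
                speed_condition=str(key[3]) or None,
            )
        )
    return curves


def write_covariates(
    records: Sequence[CovariateRecord], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "sex": r.sex,
                "age": r.age,
                "speed": r.speed,
                "mass": r.mass,
                "height": r.height,
                "cadence": r.cadence,
                "side": r.side,
                "speed_condition": r.speed_condition,
            }
            for r in records
        ],
        columns=COVARIATE_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_covariates(path: str | Path) -> list[CovariateRecord]:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"covariate CSV missing columns {missing}")
    records = []
    for i, row in frame.iterrows():
        for col in COVARIATE_COLUMNS:
            if pd.isna(row[col]):
                raise ValidationError(
                    f"missing value for {col!r} at row {int(i) + 2}"
                )
        try:
            records.append(
                CovariateRecord(
                    subject_id=str(row["subject_id"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    speed=float(row["speed"]),
                    mass=float(row["mass"]),
                    height=float(row["height"]),
                    cadence=float(row["cadence"]),
                    side=str(row["side"]),
                    speed_condition=str(row["speed_condition"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"invalid covariate row {int(i) + 2}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# fitted-model bundle: JSON manifest + array archive


def save_fit(fit: FOSRFit, path: str | Path) -> None:
    """Serialise a fit to a directory (manifest.json + arrays.npz)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "coefficients": fit.coefficients,
        "cov_fixed": fit.cov_fixed,
        "t_grid": fit.t_grid,
    }
    term_info_json: dict[str, dict] = {}
    for name, info in fit.term_info.items():
        entry = {k: v for k, v in info.items() if k != "transform"}
        if "transform" in info:
            arrays[f"transform__{name}"] = info["transform"]
            entry["transform_key"] = f"transform__{name}"
        term_info_json[name] = entry
    manifest = {
        "version": FIT_BUNDLE_VERSION,
        "outcome": fit.outcome,
        "config": fit.config.to_dict(),
        "lambdas": fit.lambdas,
        "sigma2": fit.sigma2,
        "sigma2_b": fit.sigma2_b,
        "term_info": term_info_json,
        "covariate_ranges": {k: list(v) for k, v in fit.covariate_ranges.items()},
        "covariate_quantiles": {
            k: list(v) for k, v in fit.covariate_quantiles.items()
        },
        "training_subjects": list(fit.training_subjects),
        "n_obs": fit.n_obs,
        "edf": fit.edf,
        "criterion": fit.criterion,
        "smoothing_method": fit.smoothing_method,
        "deployment": fit.deployment,
        "subject_spec_t": (
            {
                "n_basis": fit.subject_spec_t.n_basis,
                "domain": list(fit.subject_spec_t.domain),
                "degree": fit.subject_spec_t.degree,
            }
            if fit.subject_spec_t is not None
            else None
        ),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(path / "arrays.npz", **arrays)


def load_fit(path: str | Path) -> FOSRFit:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["version"] != FIT_BUNDLE_VERSION:
        raise ValidationError(
            f"unsupported fit bundle version {manifest['version']}"
        )
    with np.load(path / "arrays.npz") as arrays:
        coefficients = arrays["coefficients"]
        cov_fixed = arrays["cov_fixed"]
        t_grid = arrays["t_grid"]
        term_info = {}
        for name, entry in manifest["term_info"].items():
            info = dict(entry)
            key = info.pop("transform_key", None)
            if key is not None:
                info["transform"] = arrays[key]
            term_info[name] = info
    from gaitfosr.splines import BasisSpec

    spec_entry = manifest["subject_spec_t"]
    subject_spec = (
        BasisSpec(
            n_basis=spec_entry["n_basis"],
            domain=tuple(spec_entry["domain"]),
            degree=spec_entry["degree"],
        )
        if spec_entry
        else None
    )
    return FOSRFit(
        outcome=manifest["outcome"],
        config=ModelConfig.from_dict(manifest["config"]),
        t_grid=t_grid,
        coefficients=coefficients,
        lambdas=manifest["lambdas"],
        sigma2=manifest["sigma2"],
        cov_fixed=cov_fixed,
        term_info=term_info,
        covariate_ranges={
            k: tuple(v) for k, v in manifest["covariate_ranges"].items()
        },
        covariate_quantiles={
            k: tuple(v) for k, v in manifest["covariate_quantiles"].items()
        },
        training_subjects=tuple(manifest["training_subjects"]),
        n_obs=manifest["n_obs"],
        edf=manifest["edf"],
        criterion=manifest["criterion"],
        smoothing_method=manifest["smoothing_method"],
        sigma2_b=manifest["sigma2_b"],
        subject_spec_t=subject_spec,
        deployment=manifest["deployment"],
    )


# ---------------------------------------------------------------------------
# exports


def prediction_frame(pred: PredictedCurve) -> pd.DataFrame:
    data = {"t": pred.t_grid.astype(int), "mean": pred.mean}
    if pred.lower95 is not None:
        data["lower95"] = pred.lower95
        data["upper95"] = pred.upper95
    if pred.sd is not None:
        data["sd"] = pred.sd
    return pd.DataFrame(data)


def write_prediction(pred: PredictedCurve, path: str | Path) -> None:
    path = Path(path)
    frame = prediction_frame(pred)
    if path.suffix == ".json":
        payload = {"outcome": pred.outcome, "kind": pred.kind, "level": pred.level}
        payload.update({c: frame[c].tolist() for c in frame.columns})
        path.write_text(json.dumps(payload, indent=2))
    else:
        frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_report(report: EvaluationReport, path: str | Path) -> None:
    path = Path(path)
    rows = report.to_rows()
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_smooth_effect(effect: SmoothEffect, path: str | Path) -> None:
    rows = []
    for i, x in enumerate(effect.values):
        for j, t in enumerate(effect.t_grid):
            rows.append(
                {
                    "covariate": effect.covariate,
                    "value": x,
                    "t": int(t),
                    "estimate": effect.estimate[i, j],
                    "lower95": effect.lower95[i, j],
                    "upper95": effect.upper95[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def plot_prediction(pred: PredictedCurve, path: str | Path) -> None:
    """Export a figure of the predicted curve with its band, if any."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pred.t_grid, pred.mean, color="tab:blue", label="predicted mean")
    if pred.lower95 is not None:
        ax.fill_between(
            pred.t_grid, pred.lower95, pred.upper95,
            alpha=0.3, color="tab:blue", label=f"{pred.kind} band",
        )
    ax.set_xlabel("gait cycle (%)")
    ax.set_ylabel(pred.outcome)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
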