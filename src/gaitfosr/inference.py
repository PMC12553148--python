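"""Prediction of normative waveforms with uncertainty, and extraction of
smooth covariate-effect curves with pointwise confidence bands."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from gaitfosr.errors import CovariateRangeError, ValidationError
from gaitfosr.model import FIXED_BLOCK_ORDER, FOSRFit
from gaitfosr.records import SMOOTH_COVARIATES, CovariateRecord
from gaitfosr.splines import BasisSpec, bspline_basis


@dataclass
class PredictedCurve:
    """Population-level predicted waveform for one covariate profile."""

    outcome: str
    t_grid: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray | None = None
    upper95: np.ndarray | None = None
    sd: np.ndarray | None = None
    level: float | None = None
    kind: str | None = None
    covariates: CovariateRecord | None = None

    def __post_init__(self) -> None:
        if self.sd is not None and np.any(self.sd < 0):
            raise ValidationError("sd must be non-negative")
        if self.lower95 is not None and self.upper95 is not None:
            if np.any(self.lower95 > self.mean) or np.any(self.mean > self.upper95):
                raise ValidationError("band must contain the mean pointwise")


@dataclass
class SmoothEffect:
    """One covariate-by-time effect surface evaluated at chosen values."""

    covariate: str
    values: np.ndarray  # evaluation points in covariate units
    t_grid: np.ndarray
    estimate: np.ndarray  # shape (len(values), len(t_grid))
    lower95: np.ndarray
    upper95: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower95 > self.estimate) or np.any(self.estimate > self.upper95):
            raise ValidationError("confidence band must contain the estimate")


def _spec_from_info(info: dict) -> BasisSpec:
    return BasisSpec(
        n_basis=info["n_basis"], domain=tuple(info["domain"]), degree=info["degree"]
    )


def _check_range(fit: FOSRFit, rec: CovariateRecord) -> None:
    for name in SMOOTH_COVARIATES:
        lo, hi = fit.covariate_ranges[name]
        value = rec.covariate_value(name)
        if not (lo <= value <= hi):
            raise CovariateRangeError(
                f"{name}={value} outside supported range [{lo:.6g}, {hi:.6g}] "
                f"of the training data"
            )


def fixed_design_for_profile(fit: FOSRFit, rec: CovariateRecord) -> np.ndarray:
    """Rows of the fixed-effect design for one profile (len(t_grid) x p_fixed)."""
    _check_range(fit, rec)
    t = fit.t_grid
    n_t = t.size
    p_fixed = fit.cov_fixed.shape[0]
    design = np.zeros((n_t, p_fixed))
    for name in FIXED_BLOCK_ORDER:
        info = fit.term_info[name]
        sl = slice(info["start"], info["stop"])
        if name == "intercept_time":
            design[:, sl] = bspline_basis(t, _spec_from_info(info["spec_t"]))
        elif name in ("sex", "side"):
            indicator = rec.sex_indicator if name == "sex" else rec.side_indicator
            design[:, sl] = indicator
        else:
            covariate = name[2:]
            spec_x = _spec_from_info(info["spec_x"])
            spec_t = _spec_from_info(info["spec_t"])
            row_x = bspline_basis(np.array([rec.covariate_value(covariate)]), spec_x)
            row_xc = row_x @ info["transform"]  # 1 x (Kx - 1)
            basis_t = bspline_basis(t, spec_t)  # n_t x Kt
            # row tau <- kron(row_xc, basis_t[tau]): column j*Kt+k
            design[:, sl] = (
                row_xc[0][:, None, None] * basis_t.T[None, :, :]
            ).reshape(-1, n_t).T
    return design


def predict_mean(fit: FOSRFit, new_cov: CovariateRecord) -> PredictedCurve:
    """Population-level mean waveform (subject random curve set to zero)."""
    design = fixed_design_for_profile(fit, new_cov)
    p_fixed = fit.cov_fixed.shape[0]
    mean = design @ fit.coefficients[:p_fixed]
    return PredictedCurve(
        outcome=fit.outcome, t_grid=fit.t_grid, mean=mean, covariates=new_cov
    )


def predict_band(
    fit: FOSRFit,
    new_cov: CovariateRecord,
    level: float = 0.95,
    kind: str = "ci",
) -> PredictedCurve:
    """Predicted waveform with a pointwise uncertainty band.

    ``kind="ci"``: Wald band mean +/- z * se from the coefficient
    covariance. ``kind="sd"``: population band mean +/- sd with
    sd^2 = prediction variance + random-curve variance + residual variance.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if kind not in ("ci", "sd"):
        raise ValidationError(f"kind must be 'ci' or 'sd', got {kind!r}")
    design = fixed_design_for_profile(fit, new_cov)
    p_fixed = fit.cov_fixed.shape[0]
    mean = design @ fit.coefficients[:p_fixed]
    pred_var = np.sum((design @ fit.cov_fixed) * design, axis=1)
    if kind == "ci":
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(pred_var)
        sd = np.sqrt(pred_var)
    else:
        total_var = pred_var + fit.random_curve_variance() + fit.sigma2
        sd = np.sqrt(total_var)
        half = sd
    return PredictedCurve(
        outcome=fit.outcome,
        t_grid=fit.t_grid,
        mean=mean,
        lower95=mean - half,
        upper95=mean + half,
        sd=sd,
        level=level,
        kind=kind,
        covariates=new_cov,
    )


def covariate_quantiles(
    covariates: Sequence[CovariateRecord],
    name: str,
    probs: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> np.ndarray:
    """Empirical quantiles (linear interpolation of order statistics)."""
    if not covariates:
        raise ValidationError("empty covariate list")
    values = np.array([rec.covariate_value(name) for rec in covariates])
    return np.quantile(values, probs, method="linear")


def extract_smooth_effect(
    fit: FOSRFit,
    covariate: str,
    values: Sequence[float] | np.ndarray,
    t_grid: np.ndarray | None = None,
) -> SmoothEffect:
    """Centred effect curves f(x, t) at chosen covariate values, with a
    pointwise 95% confidence band from the block's coefficient covariance.
    """
    if covariate in ("sex", "side"):
        raise ValidationError(
            f"{covariate!r} is a scalar (time-constant) effect; read it from "
            f"fit.block_coefficients({covariate!r}) instead"
        )
    if covariate not in SMOOTH_COVARIATES:
        raise ValidationError(
            f"unknown smooth covariate {covariate!r}; "
            f"expected one of {SMOOTH_COVARIATES}"
        )
    t = fit.t_grid if t_grid is None else np.asarray(t_grid, float)
    values = np.atleast_1d(np.asarray(values, float))
    lo, hi = fit.covariate_ranges[covariate]
    if np.any(values < lo) or np.any(values > hi):
        raise CovariateRangeError(
            f"{covariate} values outside supported range [{lo:.6g}, {hi:.6g}]"
        )
    info = fit.term_info[f"f_{covariate}"]
    spec_x = _spec_from_info(info["spec_x"])
    spec_t = _spec_from_info(info["spec_t"])
    basis_x = bspline_basis(values, spec_x) @ info["transform"]  # m x (Kx-1)
    basis_t = bspline_basis(t, spec_t)  # n_t x Kt
    beta = fit.block_coefficients(f"f_{covariate}")
    cov = fit.block_covariance(f"f_{covariate}")
    n_t = t.size
    estimate = np.empty((values.size, n_t))
    se = np.empty((values.size, n_t))
    for i in range(values.size):
        rows = (basis_x[i][:, None, None] * basis_t.T[None, :, :]).reshape(-1, n_t).T
        estimate[i] = rows @ beta
        se[i] = np.sqrt(np.sum((rows @ cov) * rows, axis=1))
    z = norm.ppf(0.975)
    return SmoothEffect(
        covariate=covariate,
        values=values,
        t_grid=t,
        estimate=estimate,
        lower95=estimate - z * se,
        upper95=estimate + z * se,
    )
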