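"""Function-on-scalar model assembly and penalized least-squares fitting.

The response is the stacked long vector of all observation curves
(one row per (observation, t) pair). Fixed terms: a penalized spline in t
for the time-varying intercept, one sum-to-zero-constrained tensor-product
surface per continuous covariate, and unpenalized indicator columns for
sex and side. Subject-level random curves are per-subject coefficients on
a shared time basis with one shared ridge penalty, predicted as BLUPs.

Smoothing parameters are selected by REML via Fellner-Schall updates
(GCV via direct numerical optimisation as a fallback), or fixed through
the configuration for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from gaitfosr.errors import NumericalError, ValidationError
from gaitfosr.outcomes import N_GAIT_POINTS
from gaitfosr.records import SMOOTH_COVARIATES, CovariateRecord, GaitCurve, default_t_grid
from gaitfosr.splines import (
    BasisSpec,
    bspline_basis,
    difference_penalty,
    sum_to_zero_transform,
)

FIXED_BLOCK_ORDER = (
    "intercept_time",
    "f_age",
    "f_speed",
    "f_cadence",
    "f_height",
    "f_mass",
    "sex",
    "side",
)
RANDOM_BLOCK = "random_subject"

_LAMBDA_MIN = 1e-7
_LAMBDA_MAX = 1e7


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of bases, penalties and smoothing selection."""

    n_basis_t: int = 20
    n_basis_x: int = 8
    n_basis_tensor_t: int = 8
    n_basis_subject: int = 20
    degree: int = 3
    penalty_order: int = 2
    include_random: bool = True
    smoothing: str = "REML"  # one of REML, GCV, fixed
    lambda_default: float = 1.0
    lambda_overrides: Mapping[str, float] = field(default_factory=dict)
    domain_extension: float = 0.01
    max_iter: int = 200
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.smoothing not in ("REML", "GCV", "fixed"):
            raise ValidationError(
                f"smoothing must be REML, GCV or fixed, got {self.smoothing!r}"
            )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lambda_overrides"] = dict(self.lambda_overrides)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(**d)


@dataclass
class TermBlock:
    """One named design block with its penalties (in block coordinates)."""

    name: str
    design: sp.csr_matrix
    penalties: list[tuple[str, np.ndarray | None]]  # None => identity ridge
    cols: slice
    spec_x: BasisSpec | None = None
    spec_t: BasisSpec | None = None
    transform: np.ndarray | None = None  # sum-to-zero null-space basis Z

    @property
    def n_cols(self) -> int:
        return self.cols.stop - self.cols.start


@dataclass
class DesignBlocks:
    """Full long-format design, organised by named term blocks."""

    blocks: dict[str, TermBlock]
    t_grid: np.ndarray
    n_obs: int
    subject_ids: tuple[str, ...]  # unique, in first-appearance order

    @property
    def n_rows(self) -> int:
        return self.n_obs * self.t_grid.size

    @property
    def n_cols(self) -> int:
        return max(b.cols.stop for b in self.blocks.values())

    @property
    def fixed_cols(self) -> slice:
        stop = max(
            b.cols.stop for n, b in self.blocks.items() if n != RANDOM_BLOCK
        )
        return slice(0, stop)

    def full_matrix(self) -> sp.csr_matrix:
        ordered = sorted(self.blocks.values(), key=lambda b: b.cols.start)
        return sp.hstack([b.design for b in ordered], format="csr")

    def embedded_penalties(self) -> list["EmbeddedPenalty"]:
        pens = []
        for block in sorted(self.blocks.values(), key=lambda b: b.cols.start):
            for pen_name, matrix in block.penalties:
                pens.append(EmbeddedPenalty(pen_name, block.cols, matrix))
        return pens


@dataclass
class EmbeddedPenalty:
    """A penalty matrix embedded at a column slice of the full design."""

    name: str
    cols: slice
    matrix: np.ndarray | None  # None encodes an identity (ridge) penalty

    @property
    def dim(self) -> int:
        return self.cols.stop - self.cols.start


@dataclass
class SmoothingSelection:
    """Outcome of smoothing-parameter selection."""

    lambdas: np.ndarray
    criterion: float
    method: str
    edf: float
    iterations: int
    trace: list[dict] = field(default_factory=list)


@dataclass
class FOSRFit:
    """A fitted function-on-scalar model for a single outcome."""

    outcome: str
    config: ModelConfig
    t_grid: np.ndarray
    coefficients: np.ndarray
    lambdas: dict[str, float]
    sigma2: float
    cov_fixed: np.ndarray
    term_info: dict[str, dict]
    covariate_ranges: dict[str, tuple[float, float]]
    covariate_quantiles: dict[str, tuple[float, float, float]]
    training_subjects: tuple[str, ...]
    n_obs: int
    edf: float
    criterion: float
    smoothing_method: str
    sigma2_b: float = 0.0  # per-coefficient variance of the random curves
    subject_spec_t: BasisSpec | None = None
    deployment: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise ValidationError(f"residual variance must be positive, got {self.sigma2}")
        if any(lam < 0 for lam in self.lambdas.values()):
            raise ValidationError("smoothing parameters must be non-negative")

    @property
    def n_subjects(self) -> int:
        return len(self.training_subjects)

    def block_coefficients(self, name: str) -> np.ndarray:
        info = self.term_info[name]
        return self.coefficients[info["start"]:info["stop"]]

    def block_covariance(self, name: str) -> np.ndarray:
        info = self.term_info[name]
        if info["start"] >= self.cov_fixed.shape[0]:
            raise ValidationError(f"no stored covariance for block {name!r}")
        sl = slice(info["start"], info["stop"])
        return self.cov_fixed[sl, sl]

    def random_curve_variance(self) -> np.ndarray:
        """Pointwise variance of a subject random curve b_i(t)."""
        if self.subject_spec_t is None or self.sigma2_b == 0.0:
            return np.zeros(self.t_grid.size)
        basis = bspline_basis(self.t_grid, self.subject_spec_t)
        return self.sigma2_b * np.sum(basis**2, axis=1)


def _extended_domain(values: np.ndarray, fraction: float) -> tuple[float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    pad = fraction * (hi - lo)
    if pad == 0.0:
        pad = max(abs(lo), 1.0) * fraction
    return lo - pad, hi + pad


def assemble_design(
    covariates: Sequence[CovariateRecord],
    t_grid: np.ndarray | None = None,
    model_config: ModelConfig | None = None,
) -> DesignBlocks:
    """Build the stacked long design (n_obs * len(t_grid) rows)."""
    if not covariates:
        raise ValidationError("empty covariate list")
    for i, rec in enumerate(covariates):
        if not isinstance(rec, CovariateRecord):
            raise ValidationError(f"covariate {i} is not a CovariateRecord")
    config = model_config or ModelConfig()
    t = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    n_obs = len(covariates)
    n_t = t.size

    blocks: dict[str, TermBlock] = {}
    col = 0

    spec_t0 = BasisSpec(config.n_basis_t, (float(t[0]), float(t[-1])), config.degree)
    basis_t0 = bspline_basis(t, spec_t0)
    design = sp.kron(np.ones((n_obs, 1)), sp.csr_matrix(basis_t0), format="csr")
    pen_t0 = difference_penalty(config.n_basis_t, config.penalty_order).matrix
    blocks["intercept_time"] = TermBlock(
        "intercept_time", design, [("intercept_time", pen_t0)],
        slice(col, col + config.n_basis_t), spec_t=spec_t0,
    )
    col += config.n_basis_t

    spec_tt = BasisSpec(
        config.n_basis_tensor_t, (float(t[0]), float(t[-1])), config.degree
    )
    basis_tt = bspline_basis(t, spec_tt)
    k_t = config.n_basis_tensor_t
    pen_t_marg = difference_penalty(k_t, config.penalty_order).matrix
    for name in SMOOTH_COVARIATES:
        x = np.array([rec.covariate_value(name) for rec in covariates])
        domain = _extended_domain(x, config.domain_extension)
        spec_x = BasisSpec(config.n_basis_x, domain, config.degree)
        basis_x = bspline_basis(x, spec_x)
        transform = sum_to_zero_transform(basis_x)
        basis_xc = basis_x @ transform  # n_obs x (Kx - 1)
        k_xc = basis_xc.shape[1]
        dense = (
            basis_xc[:, None, :, None] * basis_tt[None, :, None, :]
        ).reshape(n_obs * n_t, k_xc * k_t)
        pen_x_full = difference_penalty(config.n_basis_x, config.penalty_order).matrix
        pen_x = transform.T @ pen_x_full @ transform
        block_name = f"f_{name}"
        blocks[block_name] = TermBlock(
            block_name,
            sp.csr_matrix(dense),
            [
                (f"{block_name}_x", np.kron(pen_x, np.eye(k_t))),
                (f"{block_name}_t", np.kron(np.eye(k_xc), pen_t_marg)),
            ],
            slice(col, col + k_xc * k_t),
            spec_x=spec_x,
            spec_t=spec_tt,
            transform=transform,
        )
        col += k_xc * k_t

    for name, attr in (("sex", "sex_indicator"), ("side", "side_indicator")):
        indicator = np.array([getattr(rec, attr) for rec in covariates])
        column = np.repeat(indicator, n_t)[:, None]
        blocks[name] = TermBlock(
            name, sp.csr_matrix(column), [], slice(col, col + 1)
        )
        col += 1

    subject_ids = tuple(dict.fromkeys(rec.subject_id for rec in covariates))
    if config.include_random:
        spec_b = BasisSpec(
            config.n_basis_subject, (float(t[0]), float(t[-1])), config.degree
        )
        basis_b = sp.coo_matrix(bspline_basis(t, spec_b))
        k_b = config.n_basis_subject
        subj_index = {sid: j for j, sid in enumerate(subject_ids)}
        nnz = basis_b.nnz
        rows = np.concatenate(
            [i * n_t + basis_b.row for i in range(n_obs)]
        )
        cols_ = np.concatenate(
            [subj_index[rec.subject_id] * k_b + basis_b.col for rec in covariates]
        )
        data = np.tile(basis_b.data, n_obs)
        design_b = sp.csr_matrix(
            (data, (rows, cols_)), shape=(n_obs * n_t, k_b * len(subject_ids))
        )
        blocks[RANDOM_BLOCK] = TermBlock(
            RANDOM_BLOCK,
            design_b,
            [(RANDOM_BLOCK, None)],
            slice(col, col + k_b * len(subject_ids)),
            spec_t=spec_b,
        )
        col += k_b * len(subject_ids)

    return DesignBlocks(blocks=blocks, t_grid=t, n_obs=n_obs, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# penalized least squares at fixed lambda


def _build_system(design) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(design):
        return np.asarray((design.T @ design).todense()), design
    return design.T @ design, design


def _add_penalties(
    xtx: np.ndarray, penalties: Sequence[EmbeddedPenalty], lambdas: np.ndarray
) -> np.ndarray:
    a = xtx.copy()
    for pen, lam in zip(penalties, lambdas):
        if pen.matrix is None:
            idx = np.arange(pen.cols.start, pen.cols.stop)
            a[idx, idx] += lam
        else:
            a[pen.cols, pen.cols] += lam * pen.matrix
    return a


@dataclass
class _Solution:
    beta: np.ndarray
    a_inv: np.ndarray
    rss: float
    edf: float
    sigma2: float
    lambdas: np.ndarray


def _solve_at_lambda(
    xtx: np.ndarray,
    xty: np.ndarray,
    y: np.ndarray,
    design,
    penalties: Sequence[EmbeddedPenalty],
    lambdas: np.ndarray,
) -> _Solution:
    a = _add_penalties(xtx, penalties, lambdas)
    try:
        factor = sla.cho_factor(a, lower=True, check_finite=False)
        beta = sla.cho_solve(factor, xty, check_finite=False)
        a_inv = sla.cho_solve(factor, np.eye(a.shape[0]), check_finite=False)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        # near-collinear blocks at very small lambda: fall back to the
        # minimum-norm solution (fitted values remain well defined)
        a_inv = sla.pinvh(a)
        beta = a_inv @ xty
    fitted = design @ beta
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.sum(a_inv * xtx))  # tr(A^-1 X'X), penalties symmetric
    n = y.size
    denom = max(n - edf, 1.0)
    sigma2 = rss / denom
    return _Solution(beta, a_inv, rss, edf, sigma2, np.asarray(lambdas, float))


def _penalty_groups(
    penalties: Sequence[EmbeddedPenalty],
) -> dict[tuple[int, int], list[int]]:
    groups: dict[tuple[int, int], list[int]] = {}
    for k, pen in enumerate(penalties):
        groups.setdefault((pen.cols.start, pen.cols.stop), []).append(k)
    return groups


def _trace_sinv_sk(
    penalties: Sequence[EmbeddedPenalty],
    lambdas: np.ndarray,
    groups: dict[tuple[int, int], list[int]],
) -> np.ndarray:
    """tr(S_lambda^- S_k) per penalty, block-diagonal by construction."""
    out = np.zeros(len(penalties))
    for (_, _), members in groups.items():
        if len(members) == 1 and penalties[members[0]].matrix is None:
            k = members[0]
            out[k] = penalties[k].dim / lambdas[k]
            continue
        dim = penalties[members[0]].dim
        s_block = np.zeros((dim, dim))
        for k in members:
            m = penalties[k].matrix
            s_block += lambdas[k] * (np.eye(dim) if m is None else m)
        evals, evecs = np.linalg.eigh(s_block)
        tol = max(evals[-1], 1e-300) * 1e-10
        pos = evals > tol
        w = evecs[:, pos]
        inv_d = 1.0 / evals[pos]
        for k in members:
            m = penalties[k].matrix
            mk = np.eye(dim) if m is None else m
            b = mk @ w
            out[k] = float(np.sum(np.sum(w * b, axis=0) * inv_d))
    return out


def _reml_score(
    sol: _Solution, penalties: Sequence[EmbeddedPenalty], xtx: np.ndarray, n: int
) -> float:
    """Profiled (-2 log) restricted likelihood up to an additive constant.

    With the scale parameter profiled out this reduces to
    (n - M0) * log(rss + penalty) + log|X'X + S| - log|S|_+ where M0 is
    the total penalty null-space dimension.
    """
    a = _add_penalties(xtx, penalties, sol.lambdas)
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return math.inf
    logdet_s = 0.0
    rank_s = 0
    for (start, stop), members in _penalty_groups(penalties).items():
        dim = stop - start
        s_block = np.zeros((dim, dim))
        for k in members:
            m = penalties[k].matrix
            s_block += sol.lambdas[k] * (np.eye(dim) if m is None else m)
        evals = np.linalg.eigvalsh(s_block)
        tol = max(evals[-1], 1e-300) * 1e-10
        pos = evals[evals > tol]
        logdet_s += float(np.sum(np.log(pos)))
        rank_s += pos.size
    penalty_term = 0.0
    for pen, lam in zip(penalties, sol.lambdas):
        b = sol.beta[pen.cols]
        q = float(b @ b) if pen.matrix is None else float(b @ pen.matrix @ b)
        penalty_term += lam * q
    # unpenalized columns contribute to the null space as well
    n_null = a.shape[0] - rank_s
    return float(
        (n - n_null) * math.log(max(sol.rss + penalty_term, 1e-300))
        + logdet_a
        - logdet_s
    )


def select_smoothing(
    design,
    response: np.ndarray,
    penalties: Sequence[EmbeddedPenalty],
    method: str = "REML",
    max_iter: int = 200,
    tol: float = 1e-3,
    init: np.ndarray | None = None,
) -> SmoothingSelection:
    """Choose smoothing parameters by REML (Fellner-Schall updates) or GCV.

    Raises :class:`NumericalError` carrying the iteration trace if the
    optimiser fails to converge.
    """
    if method not in ("REML", "GCV"):
        raise ValidationError(f"method must be REML or GCV, got {method!r}")
    y = np.asarray(response, float)
    xtx, design = _build_system(design)
    xty = design.T @ y
    lambdas = np.ones(len(penalties)) if init is None else np.asarray(init, float)
    groups = _penalty_groups(penalties)
    trace: list[dict] = []

    if method == "GCV":
        from scipy.optimize import minimize

        n = y.size

        def gcv(log_lam: np.ndarray) -> float:
            sol = _solve_at_lambda(xtx, xty, y, design, penalties, np.exp(log_lam))
            return n * sol.rss / (n - sol.edf) ** 2

        res = minimize(
            gcv, np.log(lambdas), method="Powell",
            options={"maxiter": max_iter * len(penalties), "xtol": 1e-3},
        )
        lambdas = np.exp(res.x)
        sol = _solve_at_lambda(xtx, xty, y, design, penalties, lambdas)
        return SmoothingSelection(
            lambdas=lambdas, criterion=float(res.fun), method="GCV",
            edf=sol.edf, iterations=int(res.nit), trace=trace,
        )

    sol = _solve_at_lambda(xtx, xty, y, design, penalties, lambdas)
    score = _reml_score(sol, penalties, xtx, y.size)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        tr_sinv = _trace_sinv_sk(penalties, lambdas, groups)
        target = lambdas.copy()
        for k, pen in enumerate(penalties):
            sl = pen.cols
            b = sol.beta[sl]
            if pen.matrix is None:
                tr_ainv = float(np.trace(sol.a_inv[sl, sl]))
                quad = float(b @ b)
            else:
                tr_ainv = float(np.sum(sol.a_inv[sl, sl] * pen.matrix))
                quad = float(b @ pen.matrix @ b)
            numer = max(tr_sinv[k] - tr_ainv, 0.0)
            if quad <= 1e-300 or numer <= 1e-12:
                target[k] = _LAMBDA_MAX
            else:
                target[k] = float(
                    np.clip(
                        lambdas[k] * sol.sigma2 * numer / quad,
                        _LAMBDA_MIN,
                        _LAMBDA_MAX,
                    )
                )
        # step-halving on the log scale, guarded by the REML score
        direction = np.log(target) - np.log(lambdas)
        step = 1.0
        improved = False
        while step >= 1.0 / 64.0:
            candidate = np.exp(np.log(lambdas) + step * direction)
            cand_sol = _solve_at_lambda(xtx, xty, y, design, penalties, candidate)
            cand_score = _reml_score(cand_sol, penalties, xtx, y.size)
            if cand_score <= score + 1e-10:
                improved = True
                break
            step /= 2.0
        if not improved:
            converged = True  # no REML improvement in the update direction
            break
        score_drop = score - cand_score
        # ignore movements of lambdas pinned at the ceiling (null effects)
        free = candidate < 0.99 * _LAMBDA_MAX
        delta = float(np.max(np.abs(step * direction[free]), initial=0.0))
        lambdas, sol, score = candidate, cand_sol, cand_score
        trace.append(
            {"iteration": iteration, "lambdas": lambdas.tolist(), "step": step,
             "rss": sol.rss, "edf": sol.edf, "reml": score, "delta": delta}
        )
        if delta < tol or score_drop < 1e-3:
            converged = True
            break
    if not converged:
        err = NumericalError(
            f"REML smoothing selection did not converge in {iteration} iterations"
        )
        err.trace = trace
        raise err
    return SmoothingSelection(
        lambdas=lambdas,
        criterion=_reml_score(sol, penalties, xtx, y.size),
        method="REML",
        edf=sol.edf,
        iterations=iteration,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# public fitting API


def _validate_pairing(
    curves: Sequence[GaitCurve], covariates: Sequence[CovariateRecord]
) -> str:
    if len(curves) != len(covariates):
        raise ValidationError(
            f"{len(curves)} curves but {len(covariates)} covariate records"
        )
    outcomes = {c.outcome for c in curves}
    if len(outcomes) != 1:
        raise ValidationError(
            f"fit_fosr handles one outcome at a time, got {sorted(outcomes)}"
        )
    for i, (curve, rec) in enumerate(zip(curves, covariates)):
        if curve.subject_id != rec.subject_id:
            raise ValidationError(
                f"curve {i} subject {curve.subject_id!r} does not match "
                f"covariate subject {rec.subject_id!r}"
            )
    return outcomes.pop()


def _lambda_vector(
    penalties: Sequence[EmbeddedPenalty], config: ModelConfig
) -> np.ndarray:
    return np.array(
        [
            float(config.lambda_overrides.get(p.name, config.lambda_default))
            for p in penalties
        ]
    )


def fit_fosr(
    curves: Sequence[GaitCurve],
    covariates: Sequence[CovariateRecord],
    model_config: ModelConfig | None = None,
    deployment: bool = False,
) -> FOSRFit:
    """Fit the penalized function-on-scalar model for one outcome."""
    config = model_config or ModelConfig()
    outcome = _validate_pairing(curves, covariates)
    t = curves[0].t_grid
    blocks = assemble_design(covariates, t, config)
    design = blocks.full_matrix()
    penalties = blocks.embedded_penalties()
    y = np.concatenate([c.values for c in curves])

    if config.smoothing == "fixed":
        lambdas = _lambda_vector(penalties, config)
        selection = None
    else:
        init = _lambda_vector(penalties, config)
        selection = select_smoothing(
            design, y, penalties, method=config.smoothing,
            max_iter=config.max_iter, tol=config.tol, init=init,
        )
        lambdas = selection.lambdas

    xtx, design = _build_system(design)
    xty = design.T @ y
    sol = _solve_at_lambda(xtx, xty, y, design, penalties, lambdas)

    fixed = blocks.fixed_cols
    cov_fixed = sol.sigma2 * sol.a_inv[fixed, fixed]

    term_info: dict[str, dict] = {}
    for name, block in blocks.blocks.items():
        info: dict = {"start": block.cols.start, "stop": block.cols.stop}
        if block.spec_x is not None:
            info["spec_x"] = {
                "n_basis": block.spec_x.n_basis,
                "domain": list(block.spec_x.domain),
                "degree": block.spec_x.degree,
            }
        if block.spec_t is not None:
            info["spec_t"] = {
                "n_basis": block.spec_t.n_basis,
                "domain": list(block.spec_t.domain),
                "degree": block.spec_t.degree,
            }
        if block.transform is not None:
            info["transform"] = block.transform
        term_info[name] = info

    lambda_dict = {p.name: float(lam) for p, lam in zip(penalties, lambdas)}
    sigma2_b = 0.0
    subject_spec = None
    if RANDOM_BLOCK in blocks.blocks:
        sigma2_b = sol.sigma2 / lambda_dict[RANDOM_BLOCK]
        subject_spec = blocks.blocks[RANDOM_BLOCK].spec_t

    ranges = {}
    quantiles = {}
    for name in SMOOTH_COVARIATES:
        spec_x = blocks.blocks[f"f_{name}"].spec_x
        ranges[name] = spec_x.domain
        values = np.array([rec.covariate_value(name) for rec in covariates])
        quantiles[name] = tuple(np.quantile(values, (0.25, 0.5, 0.75)).tolist())

    return FOSRFit(
        outcome=outcome,
        config=config,
        t_grid=np.asarray(t, float),
        coefficients=sol.beta,
        lambdas=lambda_dict,
        sigma2=sol.sigma2,
        cov_fixed=cov_fixed,
        term_info=term_info,
        covariate_ranges=ranges,
        covariate_quantiles=quantiles,
        training_subjects=blocks.subject_ids,
        n_obs=blocks.n_obs,
        edf=sol.edf,
        criterion=selection.criterion if selection else sol.rss,
        smoothing_method=config.smoothing,
        sigma2_b=sigma2_b,
        subject_spec_t=subject_spec,
        deployment=deployment,
    )


def refit_full(
    curves: Sequence[GaitCurve],
    covariates: Sequence[CovariateRecord],
    model_config: ModelConfig | None = None,
) -> FOSRFit:
    """Deployment fit on the full dataset (same pipeline as fit_fosr).

    The returned fit is flagged so evaluation against its own training
    subjects is refused unless explicitly overridden.
    """
    return fit_fosr(curves, covariates, model_config, deployment=True)
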