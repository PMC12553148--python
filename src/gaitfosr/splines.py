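"""B-spline bases, difference penalties, tensor-product blocks and
sum-to-zero constraints.

Numerical substrate for the functional additive model: every smooth term
is represented by a B-spline basis (equally spaced interior knots) with a
difference penalty on its coefficients; covariate-by-time surfaces use
row-wise Kronecker (tensor) products of two marginal bases with one
Kronecker-extended penalty per marginal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from gaitfosr.errors import NumericalError, ValidationError

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a univariate B-spline basis.

    ``n_basis`` coefficients, polynomial ``degree`` (cubic by default),
    over a closed ``domain``; interior knots are equally spaced.
    """

    n_basis: int
    domain: tuple[float, float]
    degree: int = 3

    def __post_init__(self) -> None:
        if self.n_basis < 2:
            raise ValidationError(f"n_basis must be >= 2, got {self.n_basis}")
        if self.degree < 0:
            raise ValidationError(f"degree must be >= 0, got {self.degree}")
        if self.n_basis <= self.degree:
            raise ValidationError(
                f"n_basis ({self.n_basis}) must exceed degree ({self.degree})"
            )
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValidationError(f"degenerate domain {self.domain}")

    @property
    def knots(self) -> np.ndarray:
        """Full knot vector with (degree+1)-fold boundary knots."""
        lo, hi = self.domain
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate(
            [np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)]
        )


@dataclass
class PenaltyBlock:
    """A symmetric PSD quadratic penalty on a coefficient block."""

    matrix: np.ndarray
    order: int
    null_space_dim: int = field(default=-1)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValidationError("penalty matrix must be symmetric")
        eigs = np.linalg.eigvalsh(self.matrix)
        if eigs.size and eigs[0] < -_PSD_TOL * max(1.0, eigs[-1]):
            raise ValidationError("penalty matrix must be positive semi-definite")
        if self.null_space_dim < 0:
            scale = max(eigs[-1], 1.0)
            self.null_space_dim = int(np.sum(eigs < 1e-9 * scale))

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def bspline_basis(grid: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis on ``grid``; rows sum to one (partition of unity).

    Raises a range error for points outside ``spec.domain``.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    lo, hi = spec.domain
    if np.any(grid < lo) or np.any(grid > hi):
        bad = grid[(grid < lo) | (grid > hi)][0]
        raise ValidationError(
            f"evaluation point {bad} outside basis domain [{lo}, {hi}]"
        )
    design = BSpline.design_matrix(grid, spec.knots, spec.degree).toarray()
    assert design.shape == (grid.size, spec.n_basis)
    return design


def difference_penalty(n_basis: int, order: int = 2) -> PenaltyBlock:
    """P = D'D for the ``order``-th forward-difference operator D."""
    if order < 1:
        raise ValidationError(f"difference order must be >= 1, got {order}")
    if order >= n_basis:
        raise ValidationError(
            f"difference order ({order}) must be < n_basis ({n_basis})"
        )
    diff = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyBlock(matrix=diff.T @ diff, order=order, null_space_dim=order)


def tensor_product_block(
    x_values: np.ndarray,
    t_grid: np.ndarray,
    spec_x: BasisSpec,
    spec_t: BasisSpec,
    penalty_order: int = 2,
) -> tuple[np.ndarray, list[PenaltyBlock]]:
    """Row-wise Kronecker design for a covariate-by-time surface f(x, t).

    Returns a design of shape ``(len(x_values) * len(t_grid), Kx * Kt)``
    (observation-major row order; column ``j*Kt + k`` pairs x-basis j with
    t-basis k) and the two Kronecker-extended marginal penalties
    ``[P_x (x) I, I (x) P_t]``.
    """
    x_values = np.atleast_1d(np.asarray(x_values, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    basis_x = bspline_basis(x_values, spec_x)
    basis_t = bspline_basis(t_grid, spec_t)
    n_obs, k_x = basis_x.shape
    n_t, k_t = basis_t.shape
    # obs-major long layout: row i*n_t + tau  ->  kron(basis_x[i], basis_t[tau])
    design = (
        basis_x[:, None, :, None] * basis_t[None, :, None, :]
    ).reshape(n_obs * n_t, k_x * k_t)
    pen_x = difference_penalty(k_x, penalty_order)
    pen_t = difference_penalty(k_t, penalty_order)
    penalties = [
        PenaltyBlock(np.kron(pen_x.matrix, np.eye(k_t)), order=pen_x.order),
        PenaltyBlock(np.kron(np.eye(k_x), pen_t.matrix), order=pen_t.order),
    ]
    return design, penalties


def sum_to_zero_transform(design: np.ndarray) -> np.ndarray:
    """Null-space basis Z of the empirical-mean constraint of ``design``.

    Columns of Z are orthonormal and satisfy ``mean(design @ Z, axis=0) = 0``
    for the rows used to build the constraint.
    """
    constraint = design.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(constraint)
    if not np.isfinite(norm) or norm < 1e-12:
        raise NumericalError("sum-to-zero constraint is rank deficient")
    # SVD null space of the 1 x K constraint row
    _, _, vt = np.linalg.svd(constraint, full_matrices=True)
    return vt[1:].T


def apply_sum_to_zero_constraint(
    design: np.ndarray,
    penalties: list[PenaltyBlock] | PenaltyBlock,
) -> tuple[np.ndarray, list[PenaltyBlock], np.ndarray]:
    """Reparametrise a block so its fitted effect averages to zero over
    the rows of ``design``.

    Returns ``(design @ Z, [Z' P Z ...], Z)``; full-space coefficients are
    recovered as ``Z @ beta_constrained``.
    """
    single = isinstance(penalties, PenaltyBlock)
    penalty_list = [penalties] if single else list(penalties)
    design = np.asarray(design, dtype=float)
    for pen in penalty_list:
        if pen.dim != design.shape[1]:
            raise ValidationError(
                f"penalty dimension {pen.dim} does not match design "
                f"column count {design.shape[1]}"
            )
    transform = sum_to_zero_transform(design)
    constrained_design = design @ transform
    constrained_penalties = [
        PenaltyBlock(transform.T @ pen.matrix @ transform, order=pen.order)
        for pen in penalty_list
    ]
    return constrained_design, constrained_penalties, transform
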