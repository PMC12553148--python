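"""Shared fixtures: small model configurations and simulated fits."""

from __future__ import annotations

import numpy as np
import pytest

from gaitfosr.model import ModelConfig, fit_fosr
from gaitfosr.records import default_t_grid
from gaitfosr.simulate import SimulationTruth, default_truth, generate_cohort


def zero_fn(x, t):
    return np.zeros_like(np.asarray(t, dtype=float))


def make_truth(
    beta0=None,
    beta_sex: float = 0.0,
    beta_side: float = 0.0,
    sigma_b: float = 0.0,
    sigma_eps: float = 0.0,
    outcome: str = "hip_sagittal_angle",
    **smooths,
) -> SimulationTruth:
    """Truth with all terms zero unless overridden."""
    if beta0 is None:
        beta0 = lambda t: np.zeros_like(np.asarray(t, float))
    terms = {f"f_{name}": zero_fn for name in ("age", "speed", "cadence", "height", "mass")}
    terms.update({f"f_{k}": v for k, v in smooths.items()})
    return SimulationTruth(
        beta0=beta0,
        beta_sex=beta_sex,
        beta_side=beta_side,
        sigma_b=sigma_b,
        sigma_eps=sigma_eps,
        outcome=outcome,
        **terms,
    )


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    return ModelConfig(
        n_basis_t=10, n_basis_x=5, n_basis_tensor_t=5, n_basis_subject=5
    )


@pytest.fixture(scope="session")
def trained():
    """A moderate REML fit on a default-truth cohort, shared across tests.

    Returns (truth, covariates, curves, fit).
    """
    config = ModelConfig(
        n_basis_t=12, n_basis_x=6, n_basis_tensor_t=6, n_basis_subject=6
    )
    truth = default_truth(sigma_eps=0.3, sigma_b=0.5)
    covariates, curves = generate_cohort(80, 42, truth)
    fit = fit_fosr(curves, covariates, config)
    return truth, covariates, curves, fit


@pytest.fixture
def t_grid() -> np.ndarray:
    return default_t_grid()
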