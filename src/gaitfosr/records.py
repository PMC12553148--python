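"""Core record types: one covariate profile and one waveform per observation.

Indicator coding convention (stable across fits): sex male=0 / female=1,
side left=0 / right=1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitfosr.errors import ValidationError
from gaitfosr.outcomes import N_GAIT_POINTS, OUTCOMES, outcome_units

SEXES = ("male", "female")
SIDES = ("left", "right")
SPEED_CONDITIONS = ("slow", "comfortable", "fast")

AGE_MIN = 3.0
AGE_MAX = 91.0

#: names of the five continuous covariates modelled as tensor-product smooths
SMOOTH_COVARIATES = ("age", "speed", "cadence", "height", "mass")


@dataclass(frozen=True)
class CovariateRecord:
    """Seven scalar covariates plus identifiers for one observation."""

    subject_id: str
    sex: str
    age: float
    speed: float
    mass: float
    height: float
    cadence: float
    side: str
    speed_condition: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.speed_condition not in SPEED_CONDITIONS:
            raise ValidationError(
                f"speed_condition must be one of {SPEED_CONDITIONS}, "
                f"got {self.speed_condition!r}"
            )
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValidationError(
                f"age must lie in [{AGE_MIN}, {AGE_MAX}] years, got {self.age}"
            )
        for name in ("speed", "mass", "height", "cadence"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be strictly positive, got {value}")

    @property
    def sex_indicator(self) -> float:
        return float(self.sex == "female")

    @property
    def side_indicator(self) -> float:
        return float(self.side == "right")

    def covariate_value(self, name: str) -> float:
        """Value of one of the five continuous smooth covariates."""
        if name not in SMOOTH_COVARIATES:
            raise KeyError(f"not a smooth covariate: {name!r}")
        return float(getattr(self, name))


def default_t_grid() -> np.ndarray:
    """The 100-point gait-cycle grid 0..99 (percent, half-open [0, 100))."""
    return np.arange(N_GAIT_POINTS, dtype=float)


@dataclass
class GaitCurve:
    """One outcome trajectory for one observation: 100 time-normalised values."""

    subject_id: str
    outcome: str
    values: np.ndarray
    t_grid: np.ndarray = field(default_factory=default_t_grid)
    units: str | None = None
    # optional observation metadata, used to key curves in the long CSV
    side: str | None = None
    speed_condition: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.values.shape != (N_GAIT_POINTS,):
            raise ValidationError(
                f"curve must have exactly {N_GAIT_POINTS} values, "
                f"got shape {self.values.shape}"
            )
        if self.t_grid.shape != (N_GAIT_POINTS,):
            raise ValidationError("t_grid must have exactly 100 points")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("curve values must all be finite")
        expected = outcome_units(self.outcome)
        if self.units is None:
            self.units = expected
        elif self.units != expected:
            raise ValidationError(
                f"units {self.units!r} inconsistent with outcome "
                f"{self.outcome!r} (expected {expected!r})"
            )
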