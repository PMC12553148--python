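"""Synthetic lifespan gait cohorts with known ground-truth effect surfaces.

Generates covariate tables (three speed conditions per subject, 30% below
and above the comfortable speed) and 100-point waveforms from an additive
truth: a time-varying intercept, five covariate-by-time surfaces, constant
sex and side effects, smooth subject-level random curves and i.i.d.
Gaussian noise. Every effect surface is (approximately) centred over the
covariate sampling distribution at each time point, matching the
identifiability convention of the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from gaitfosr.errors import CovariateRangeError, ValidationError
from gaitfosr.outcomes import OUTCOME_FAMILY, OUTCOMES, outcome_units
from gaitfosr.records import (
    AGE_MAX,
    AGE_MIN,
    SIDES,
    SMOOTH_COVARIATES,
    SPEED_CONDITIONS,
    CovariateRecord,
    GaitCurve,
    default_t_grid,
)

#: relative speed multipliers per condition (30% slower / faster than comfortable)
SPEED_MULTIPLIERS = {"slow": 0.7, "comfortable": 1.0, "fast": 1.3}

#: typical waveform amplitude per outcome family, in outcome units
FAMILY_SCALE = {"angle": 10.0, "grf": 1.0, "moment": 0.4, "power": 1.0}

_PROBE_SEED = 987_654_321  # internal seed for centring-moment estimation
_AGE_TURNING_POINT = 48.0


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the covariate sampler."""

    age_range: tuple[float, float] = (AGE_MIN, AGE_MAX)
    adult_age: float = 18.0
    comfortable_speed_sd: float = 0.13
    cadence_sd: float = 6.0
    bmi_sd: float = 1.8


@dataclass
class SimulationTruth:
    """Ground-truth components of the generating model for one outcome."""

    beta0: Callable[[np.ndarray], np.ndarray]
    f_age: Callable[[float, np.ndarray], np.ndarray]
    f_speed: Callable[[float, np.ndarray], np.ndarray]
    f_cadence: Callable[[float, np.ndarray], np.ndarray]
    f_height: Callable[[float, np.ndarray], np.ndarray]
    f_mass: Callable[[float, np.ndarray], np.ndarray]
    beta_sex: float
    beta_side: float
    sigma_b: float
    sigma_eps: float
    outcome: str = "hip_sagittal_angle"
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    subject_intercepts: dict[str, np.ndarray] = field(default_factory=dict)
    age_turning_point: float = _AGE_TURNING_POINT

    def smooth_term(self, name: str) -> Callable[[float, np.ndarray], np.ndarray]:
        if name not in SMOOTH_COVARIATES:
            raise KeyError(f"not a smooth covariate: {name!r}")
        return getattr(self, f"f_{name}")

    def check_range(self, rec: CovariateRecord) -> None:
        for name in SMOOTH_COVARIATES:
            if name not in self.ranges:
                continue
            lo, hi = self.ranges[name]
            value = rec.covariate_value(name)
            if not (lo <= value <= hi):
                raise CovariateRangeError(
                    f"{name}={value} outside supported range [{lo}, {hi}]"
                )

    def describe(self, t_grid: np.ndarray | None = None) -> dict:
        """JSON-serialisable summary for test introspection."""
        t = default_t_grid() if t_grid is None else np.asarray(t_grid, float)
        return {
            "outcome": self.outcome,
            "beta_sex": self.beta_sex,
            "beta_side": self.beta_side,
            "sigma_b": self.sigma_b,
            "sigma_eps": self.sigma_eps,
            "age_turning_point": self.age_turning_point,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "beta0": self.beta0(t).tolist(),
            "n_subject_intercepts": len(self.subject_intercepts),
        }


def _adult_height(sex: str, rng: np.random.Generator) -> float:
    base = 1.78 if sex == "male" else 1.65
    return base + rng.normal(0.0, 0.06)


def sample_covariates(
    n_subjects: int,
    seed: int,
    config: CohortConfig | None = None,
) -> list[CovariateRecord]:
    """Draw a cohort: three records per subject, one per speed condition.

    Slow and fast speeds are exactly 0.7x and 1.3x the comfortable speed;
    cadence rises with speed; height and mass follow an age-dependent
    growth curve below ``config.adult_age``. Deterministic given ``seed``.
    """
    if not isinstance(n_subjects, (int, np.integer)) or n_subjects < 1:
        raise ValidationError(f"n_subjects must be a positive integer, got {n_subjects}")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    records: list[CovariateRecord] = []
    obs_index = 0
    for i in range(n_subjects):
        subject_id = f"S{i + 1:04d}"
        age = float(rng.uniform(*config.age_range))
        sex = "male" if rng.random() < 0.5 else "female"
        h_adult = _adult_height(sex, rng)
        if age < config.adult_age:
            height = 0.52 + (h_adult - 0.52) * (age / config.adult_age) ** 0.75
        else:
            height = h_adult
        bmi = max(12.0, 15.5 + 7.5 * min(age, 30.0) / 30.0 + rng.normal(0.0, config.bmi_sd))
        mass = bmi * height**2
        v_comf = float(
            np.clip(
                1.05 + 0.30 * (1.0 - np.exp(-age / 10.0))
                + rng.normal(0.0, config.comfortable_speed_sd),
                0.5,
                2.0,
            )
        )
        cadence_noise = rng.normal(0.0, config.cadence_sd)
        for condition in SPEED_CONDITIONS:
            speed = SPEED_MULTIPLIERS[condition] * v_comf
            cadence = max(
                30.0,
                60.0 + 42.0 * speed + 20.0 * np.exp(-age / 12.0) + cadence_noise,
            )
            records.append(
                CovariateRecord(
                    subject_id=subject_id,
                    sex=sex,
                    age=age,
                    speed=speed,
                    mass=mass,
                    height=height,
                    cadence=cadence,
                    side=SIDES[obs_index % 2],
                    speed_condition=condition,
                )
            )
            obs_index += 1
    return records


def _probe_moments(config: CohortConfig | None = None) -> dict[str, tuple[float, float]]:
    """(mean, sd) of each smooth covariate under the sampler, for centring."""
    records = sample_covariates(2000, _PROBE_SEED, config)
    moments = {}
    for name in SMOOTH_COVARIATES:
        values = np.array([r.covariate_value(name) for r in records])
        moments[name] = (float(values.mean()), float(values.std()))
    return moments


def default_truth(
    outcome: str = "hip_sagittal_angle",
    sigma_b: float | None = None,
    sigma_eps: float | None = None,
    config: CohortConfig | None = None,
) -> SimulationTruth:
    """Default generating model for one outcome.

    The age surface is quadratic with a turning point near 48 years; the
    speed surface is monotone in speed with its largest effect early in
    the cycle; amplitudes scale with the outcome family's typical range.
    """
    scale = FAMILY_SCALE[OUTCOME_FAMILY[outcome]]
    if sigma_b is None:
        sigma_b = 0.2 * scale
    if sigma_eps is None:
        sigma_eps = 0.15 * scale
    moments = _probe_moments(config)
    cfg = config or CohortConfig()
    age_lo, age_hi = cfg.age_range
    # E[(A - c)^2] for A ~ U(age_lo, age_hi), exact
    c = _AGE_TURNING_POINT
    e_sq = ((age_hi - c) ** 3 - (age_lo - c) ** 3) / (3.0 * (age_hi - age_lo))
    m_speed, sd_speed = moments["speed"]
    m_cad, sd_cad = moments["cadence"]
    m_ht, sd_ht = moments["height"]
    m_mass, sd_mass = moments["mass"]

    def beta0(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return scale * (
            1.2 * np.sin(2 * np.pi * t / 100.0)
            + 0.8 * np.exp(-(((t - 65.0) / 12.0) ** 2))
            + 0.3
        )

    def f_age(a, t):
        t = np.asarray(t, float)
        shape = (e_sq - (np.asarray(a, float) - c) ** 2) / e_sq
        mod = 0.5 + 0.5 * np.sin(2 * np.pi * t / 100.0 + 1.0)
        return 0.35 * scale * shape * mod

    def f_speed(v, t):
        t = np.asarray(t, float)
        u = (np.asarray(v, float) - m_speed) / max(sd_speed, 1e-9)
        shape = u + 0.15 * (u**2 - 1.0)
        mod = np.exp(-(((t - 10.0) / 20.0) ** 2))
        return 0.5 * scale * shape * mod

    def f_cadence(x, t):
        t = np.asarray(t, float)
        u = (np.asarray(x, float) - m_cad) / max(sd_cad, 1e-9)
        return 0.2 * scale * u * np.cos(2 * np.pi * t / 100.0)

    def f_height(x, t):
        t = np.asarray(t, float)
        u = (np.asarray(x, float) - m_ht) / max(sd_ht, 1e-9)
        return 0.15 * scale * u * np.sin(4 * np.pi * t / 100.0)

    def f_mass(x, t):
        t = np.asarray(t, float)
        u = (np.asarray(x, float) - m_mass) / max(sd_mass, 1e-9)
        return 0.15 * scale * u * np.exp(-(((t - 50.0) / 25.0) ** 2))

    ranges = {
        "age": (age_lo, age_hi),
        "speed": (0.2, 3.0),
        "cadence": (30.0, 220.0),
        "height": (0.4, 2.3),
        "mass": (5.0, 160.0),
    }
    return SimulationTruth(
        beta0=beta0,
        f_age=f_age,
        f_speed=f_speed,
        f_cadence=f_cadence,
        f_height=f_height,
        f_mass=f_mass,
        beta_sex=0.12 * scale,
        beta_side=0.06 * scale,
        sigma_b=sigma_b,
        sigma_eps=sigma_eps,
        outcome=outcome,
        ranges=ranges,
    )


def default_truths(
    outcomes: tuple[str, ...] = OUTCOMES,
    config: CohortConfig | None = None,
) -> dict[str, SimulationTruth]:
    return {o: default_truth(o, config=config) for o in outcomes}


def _draw_subject_intercept(sigma_b: float, rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Smooth zero-mean random curve with pointwise SD sigma_b."""
    z = rng.normal(size=3)
    phase = 2 * np.pi * t / 100.0
    return (sigma_b / np.sqrt(3.0)) * (
        z[0] + np.sqrt(2.0) * z[1] * np.cos(phase) + np.sqrt(2.0) * z[2] * np.sin(phase)
    )


def true_mean_curve(
    rec: CovariateRecord,
    truth: SimulationTruth,
    include_subject: bool = False,
) -> GaitCurve:
    """Noise-free model curve for one covariate profile.

    beta0(t) + sum of smooth terms + sex and side offsets, plus the
    subject's random curve when ``include_subject`` is set (the subject
    must have been materialised by :func:`generate_cohort`, unless
    ``sigma_b`` is zero).
    """
    truth.check_range(rec)
    t = default_t_grid()
    values = truth.beta0(t).astype(float).copy()
    for name in SMOOTH_COVARIATES:
        values += truth.smooth_term(name)(rec.covariate_value(name), t)
    values += truth.beta_sex * rec.sex_indicator
    values += truth.beta_side * rec.side_indicator
    if include_subject:
        if rec.subject_id in truth.subject_intercepts:
            values += truth.subject_intercepts[rec.subject_id]
        elif truth.sigma_b != 0.0:
            raise ValidationError(
                f"no stored random curve for subject {rec.subject_id!r}; "
                "generate the cohort first or set sigma_b=0"
            )
    return GaitCurve(
        subject_id=rec.subject_id,
        outcome=truth.outcome,
        values=values,
        units=outcome_units(truth.outcome),
    )


def generate_cohort(
    n_subjects: int,
    seed: int,
    truth: SimulationTruth | Mapping[str, SimulationTruth],
    config: CohortConfig | None = None,
) -> tuple[list[CovariateRecord], list[GaitCurve]]:
    """Sample covariates and noisy waveforms for one or more outcomes.

    Each record's curve is its true mean (with the subject's random
    curve) plus i.i.d. Gaussian noise of SD ``sigma_eps`` per grid point.
    Subject random curves are drawn once per (outcome, subject) and stored
    on the truth object. Fully reproducible given ``seed``.
    """
    truths: Mapping[str, SimulationTruth]
    if isinstance(truth, SimulationTruth):
        truths = {truth.outcome: truth}
    else:
        truths = truth
        for name, tr in truths.items():
            if tr.outcome != name:
                raise ValidationError(
                    f"truth mapping key {name!r} does not match truth.outcome "
                    f"{tr.outcome!r}"
                )
    covariates = sample_covariates(n_subjects, seed, config)
    subject_ids = list(dict.fromkeys(r.subject_id for r in covariates))
    t = default_t_grid()
    curves: list[GaitCurve] = []
    for k, (name, tr) in enumerate(sorted(truths.items())):
        rng = np.random.default_rng([seed, 1 + k])
        tr.subject_intercepts.clear()
        for sid in subject_ids:
            tr.subject_intercepts[sid] = _draw_subject_intercept(tr.sigma_b, rng, t)
        for rec in covariates:
            mean = true_mean_curve(rec, tr, include_subject=True).values
            noisy = mean + rng.normal(0.0, tr.sigma_eps, size=t.size)
            curves.append(
                GaitCurve(
                    subject_id=rec.subject_id,
                    outcome=name,
                    values=noisy,
                    units=outcome_units(name),
                    side=rec.side,
                    speed_condition=rec.speed_condition,
                )
            )
    return covariates, curves
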