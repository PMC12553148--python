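"""Controlled vocabulary of the 16 waveform outcomes and their units."""

from __future__ import annotations

# family -> units; kinetic families are body-mass normalised
UNITS_BY_FAMILY = {
    "angle": "deg",
    "grf": "N/kg",
    "moment": "Nm/kg",
    "power": "W/kg",
}

# outcome name -> family
OUTCOME_FAMILY = {
    "hip_sagittal_angle": "angle",
    "hip_frontal_angle": "angle",
    "hip_transverse_angle": "angle",
    "knee_sagittal_angle": "angle",
    "ankle_sagittal_angle": "angle",
    "ankle_frontal_angle": "angle",
    "grf_ap": "grf",
    "grf_vertical": "grf",
    "hip_sagittal_moment": "moment",
    "hip_frontal_moment": "moment",
    "hip_transverse_moment": "moment",
    "knee_sagittal_moment": "moment",
    "ankle_sagittal_moment": "moment",
    "hip_sagittal_power": "power",
    "knee_sagittal_power": "power",
    "ankle_sagittal_power": "power",
}

OUTCOMES = tuple(OUTCOME_FAMILY)

#: number of time-normalised samples per gait cycle, indexed 0..99
N_GAIT_POINTS = 100


def outcome_units(outcome: str) -> str:
    """Return the measurement units for a named outcome."""
    try:
        return UNITS_BY_FAMILY[OUTCOME_FAMILY[outcome]]
    except KeyError:
        raise KeyError(
            f"unknown outcome {outcome!r}; expected one of {sorted(OUTCOMES)}"
        ) from None
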