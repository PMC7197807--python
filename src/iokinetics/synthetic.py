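"""Synthetic gamma-scan data with the statistical structure the pipeline
assumes: model-generated ROI curves distorted by a per-patient detector
gain, multiplicative measurement noise, and a flat additive background.

The generator exists so that every downstream stage (background
subtraction, normalization, agreement scoring, fitting) can be exercised
end-to-end and scored against known ground truth. Randomness is fully
reproducible: each patient draws from substreams derived from the master
seed and the patient index, so permuting or subsetting a cohort never
changes an individual patient's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    BiokineticParameters,
    I131_HALF_LIFE_H,
    PATIENT_PARAMETER_ROWS,
    Trajectory,
    ValidationError,
    patient_parameters,
    solve_trajectory,
)
from .observation import (
    MeasurementSet,
    ROI_LABELS,
    ROI_STOMACH,
    ScanSchedule,
    project_observables,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticPatient",
    "sample_parameters",
    "generate_patient",
    "generate_cohort",
]

_DEFAULT_RANGES = {
    "t_stomach_h": (0.30, 1.30),
    "t_bfwb_h": (10.0, 15.0),
    "t_thyroid_h": (35.0, 50.0),
    "i23": (0.04, 0.50),
}

_INITIAL_STATE = np.array([1.0, 0.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort size, scan schedule, parameter source, and noise model.

    ``parameter_source`` is either ``"fixed"`` (cycle through the shipped
    nine-patient parameter rows) or ``"range"`` (draw each free parameter
    uniformly from ``parameter_ranges``).
    """

    n_patients: int = 9
    schedule: ScanSchedule = field(default_factory=ScanSchedule)
    parameter_source: str = "fixed"
    parameter_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )
    noise_cov: float = 0.05
    gain_range: tuple[float, float] = (0.5, 5.0)
    background_frac: float = 0.02
    physical_half_life_h: float = I131_HALF_LIFE_H
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.parameter_source not in ("fixed", "range"):
            raise ValidationError(
                f"parameter_source must be 'fixed' or 'range', got "
                f"{self.parameter_source!r}"
            )
        if self.noise_cov < 0:
            raise ValidationError("noise_cov must be >= 0")
        low, high = self.gain_range
        if not (0 < low <= high):
            raise ValidationError("gain_range bounds must be positive and ordered")
        if self.background_frac < 0:
            raise ValidationError("background_frac must be >= 0")
        if self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")
        for name in ("t_stomach_h", "t_bfwb_h", "t_thyroid_h", "i23"):
            if name not in self.parameter_ranges:
                raise ValidationError(f"parameter_ranges missing {name}")
            lo, hi = self.parameter_ranges[name]
            if lo > hi:
                raise ValidationError(f"range for {name} must be ordered")


@dataclass(frozen=True)
class SyntheticPatient:
    """Ground truth plus the raw (distorted) measurements for one patient."""

    true_params: BiokineticParameters
    raw: MeasurementSet
    truth_trajectory: Trajectory


def _substream(seed: int, draw_index: int, stream: int) -> np.random.Generator:
    # (seed, patient, stream) keys give independent, order-insensitive draws
    return np.random.default_rng(np.random.SeedSequence([seed, draw_index, stream]))


def sample_parameters(
    config: GeneratorConfig, draw_index: int
) -> BiokineticParameters:
    """Parameters for the ``draw_index``-th patient.

    Fixed mode returns the indexed shipped parameter row verbatim; range
    mode draws each free parameter uniformly from its configured range
    using a per-patient substream.
    """
    if draw_index < 0:
        raise ValidationError("draw_index must be >= 0")
    if config.parameter_source == "fixed":
        if draw_index >= len(PATIENT_PARAMETER_ROWS):
            raise ValidationError(
                f"fixed-source index {draw_index} out of range "
                f"(have {len(PATIENT_PARAMETER_ROWS)} rows)"
            )
        row = PATIENT_PARAMETER_ROWS[draw_index]
        return patient_parameters(*row, config.physical_half_life_h)
    rng = _substream(config.seed, draw_index, 0)
    drawn = {
        name: float(rng.uniform(*config.parameter_ranges[name]))
        for name in ("t_stomach_h", "t_bfwb_h", "t_thyroid_h", "i23")
    }
    return patient_parameters(
        drawn["t_stomach_h"],
        drawn["t_bfwb_h"],
        drawn["t_thyroid_h"],
        drawn["i23"],
        config.physical_half_life_h,
    )


def generate_patient(
    params: BiokineticParameters,
    config: GeneratorConfig,
    draw_index: int,
) -> SyntheticPatient:
    """Simulate one patient's raw scan series from known parameters.

    The noise-free ROI projection is scaled by a patient-specific gain,
    perturbed multiplicatively (``value * max(1 + eps, 0)`` with
    ``eps ~ Normal(0, noise_cov)``), and offset by a flat background equal
    to ``background_frac`` times the gained first stomach value. The same
    background is emitted as a BKG series so the net-rate and
    normalization stages are exercised end-to-end.
    """
    times = np.asarray(config.schedule.times_h)
    truth = solve_trajectory(params, _INITIAL_STATE, times)
    clean = project_observables(truth, config.schedule, patient_id=f"P{draw_index + 1}")

    rng = _substream(config.seed, draw_index, 1)
    gain = float(rng.uniform(*config.gain_range))
    background = config.background_frac * gain * clean.series[ROI_STOMACH][0]
    series = {}
    for roi in ROI_LABELS:
        eps = rng.normal(0.0, config.noise_cov, size=times.size) if config.noise_cov > 0 else np.zeros(times.size)
        series[roi] = gain * clean.series[roi] * np.maximum(1.0 + eps, 0.0) + background
    raw = MeasurementSet(
        patient_id=clean.patient_id,
        schedule=config.schedule,
        series=series,
        normalized=False,
        background=np.full(times.size, background) if background > 0 else None,
    )
    return SyntheticPatient(true_params=params, raw=raw, truth_trajectory=truth)


def generate_cohort(config: GeneratorConfig) -> list[SyntheticPatient]:
    """Generate ``config.n_patients`` independent synthetic patients."""
    cohort = []
    for index in range(config.n_patients):
        params = sample_parameters(config, index)
        cohort.append(generate_patient(params, config, index))
    return cohort
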