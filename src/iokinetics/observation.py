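"""Gamma-scan observation model: ROI projection, background subtraction,
normalization, and the RMS agreement index.

Three regions of interest are carried through the pipeline: ``St``
(stomach), ``Th`` (thyroid), and ``BFWB`` (body fluid plus whole body,
one composite region on the planar scan). Raw values are count rates per
pixel; after normalization everything is dimensionless, anchored to the
stomach value at the first scan time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import (
    BODY_FLUID,
    STOMACH,
    THYROID,
    WHOLE_BODY,
    Trajectory,
    ValidationError,
)

__all__ = [
    "ROI_STOMACH",
    "ROI_THYROID",
    "ROI_BODY",
    "ROI_LABELS",
    "DEFAULT_SCAN_TIMES_H",
    "ClampWarning",
    "NormalizationError",
    "ScanSchedule",
    "MeasurementSet",
    "ATReport",
    "net_count_rate",
    "subtract_background",
    "project_observables",
    "normalize_dataset",
    "at_index",
    "at_total",
    "compute_at_report",
]

ROI_STOMACH = "St"
ROI_THYROID = "Th"
ROI_BODY = "BFWB"
ROI_LABELS = (ROI_STOMACH, ROI_THYROID, ROI_BODY)

DEFAULT_SCAN_TIMES_H: tuple[float, ...] = (1.0, 4.0, 24.0, 48.0, 72.0, 168.0)


class ClampWarning(UserWarning):
    """Background exceeded the gross rate; the net rate was clamped to zero."""


class NormalizationError(ValueError):
    """The dataset cannot be normalized (zero stomach anchor)."""


@dataclass(frozen=True)
class ScanSchedule:
    """Ordered post-administration scan times in hours."""

    times_h: tuple[float, ...] = DEFAULT_SCAN_TIMES_H

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times_h)
        if len(times) == 0:
            raise ValidationError("schedule must contain at least one scan time")
        if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"scan times must be strictly increasing and positive, got {times}"
            )
        object.__setattr__(self, "times_h", times)

    @property
    def n_scans(self) -> int:
        return len(self.times_h)


@dataclass
class MeasurementSet:
    """Per-patient ROI time series on a scan schedule.

    ``series`` maps each ROI label to one value per scan. ``background``,
    when present, holds the per-scan background rate (same units as the
    raw series) still to be subtracted.
    """

    patient_id: str
    schedule: ScanSchedule
    series: dict[str, np.ndarray]
    normalized: bool = False
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [r for r in ROI_LABELS if r not in self.series]
        if missing:
            raise ValidationError(f"missing ROI series: {missing}")
        unknown = [r for r in self.series if r not in ROI_LABELS]
        if unknown:
            raise ValidationError(f"unknown ROI labels: {unknown}")
        clean: dict[str, np.ndarray] = {}
        for roi in ROI_LABELS:
            values = np.asarray(self.series[roi], dtype=float)
            if values.shape != (self.schedule.n_scans,):
                raise ValidationError(
                    f"ROI {roi} has {values.size} values for "
                    f"{self.schedule.n_scans} scan times"
                )
            if np.any(values < 0) or not np.all(np.isfinite(values)):
                raise ValidationError(f"ROI {roi} values must be finite and >= 0")
            clean[roi] = values
        self.series = clean
        if self.background is not None:
            bkg = np.asarray(self.background, dtype=float)
            if bkg.shape != (self.schedule.n_scans,):
                raise ValidationError("background series length mismatch")
            if np.any(bkg < 0):
                raise ValidationError("background values must be >= 0")
            self.background = bkg
        if self.normalized:
            if self.background is not None:
                raise ValidationError("normalized data cannot carry a background")
            if self.series[ROI_STOMACH][0] != 1.0:
                raise ValidationError(
                    "normalized data must have St = 1.0 at the first scan"
                )


@dataclass(frozen=True)
class ATReport:
    """Agreement indices per ROI and their quadratic-mean total."""

    at_st: float
    at_th: float
    at_bfwb: float
    at_total: float
    n: int

    def __post_init__(self) -> None:
        for name in ("at_st", "at_th", "at_bfwb", "at_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        expected = at_total(self.at_st, self.at_th, self.at_bfwb)
        if abs(self.at_total - expected) > 1e-12:
            raise ValidationError(
                f"at_total {self.at_total} inconsistent with components ({expected})"
            )


def net_count_rate(gross, background):
    """Background-subtracted count rate, clamped at zero.

    Accepts scalars or arrays. A :class:`ClampWarning` is emitted when
    the background exceeds the gross rate anywhere.
    """
    gross = np.asarray(gross, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(gross < 0) or np.any(background < 0):
        raise ValidationError("gross and background rates must be >= 0")
    net = gross - background
    if np.any(net < 0):
        warnings.warn(
            "background exceeds gross count rate; net rate clamped to 0",
            ClampWarning,
            stacklevel=2,
        )
        net = np.maximum(net, 0.0)
    if net.ndim == 0:
        return float(net)
    return net


def subtract_background(measurements: MeasurementSet) -> MeasurementSet:
    """Apply :func:`net_count_rate` to every ROI series using the attached
    background; a no-op when no background is present."""
    if measurements.normalized:
        raise ValidationError("cannot subtract background from normalized data")
    if measurements.background is None:
        return measurements
    series = {
        roi: np.asarray(net_count_rate(values, measurements.background))
        for roi, values in measurements.series.items()
    }
    return MeasurementSet(
        patient_id=measurements.patient_id,
        schedule=measurements.schedule,
        series=series,
        normalized=False,
        background=None,
    )


def project_observables(
    traj: Trajectory,
    schedule: ScanSchedule | None = None,
    patient_id: str = "model",
) -> MeasurementSet:
    """Map a model trajectory onto the three scan ROIs.

    St tracks the stomach compartment, Th the thyroid, and BFWB the sum
    of body fluid and whole body. The excretion compartment is voided
    between scans and does not appear in any ROI.
    """
    if schedule is None:
        schedule = ScanSchedule(tuple(traj.times_h))
    elif tuple(traj.times_h) != schedule.times_h:
        raise ValidationError("trajectory times do not match the scan schedule")
    series = {
        ROI_STOMACH: traj.q[:, STOMACH].copy(),
        ROI_THYROID: traj.q[:, THYROID].copy(),
        ROI_BODY: traj.q[:, BODY_FLUID] + traj.q[:, WHOLE_BODY],
    }
    return MeasurementSet(
        patient_id=patient_id, schedule=schedule, series=series, normalized=False
    )


def normalize_dataset(raw: MeasurementSet) -> MeasurementSet:
    """Divide every ROI series by the stomach value at the first scan.

    The operation is idempotent and cancels any multiplicative detector
    gain. Raises :class:`NormalizationError` when the anchor is zero.
    """
    if raw.background is not None:
        raise ValidationError(
            "subtract the background (subtract_background) before normalizing"
        )
    anchor = raw.series[ROI_STOMACH][0]
    if anchor <= 0:
        raise NormalizationError(
            f"first stomach value must be > 0 to normalize, got {anchor}"
        )
    series = {roi: values / anchor for roi, values in raw.series.items()}
    series[ROI_STOMACH][0] = 1.0  # exact anchor despite x/x round-off
    return MeasurementSet(
        patient_id=raw.patient_id,
        schedule=raw.schedule,
        series=series,
        normalized=True,
    )


def at_index(observed, predicted) -> float:
    """RMS disagreement between two equal-length normalized series.

    Zero means perfect agreement; the index scales linearly with the
    series and shares their (dimensionless) units.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValidationError(
            f"series shapes differ: {observed.shape} vs {predicted.shape}"
        )
    if observed.size == 0:
        raise ValidationError("series must contain at least one point")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def at_total(at_st: float, at_th: float, at_bfwb: float) -> float:
    """Quadratic mean of the three per-ROI agreement indices."""
    for name, value in (("at_st", at_st), ("at_th", at_th), ("at_bfwb", at_bfwb)):
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    return math.sqrt((at_st**2 + at_th**2 + at_bfwb**2) / 3.0)


def compute_at_report(
    observed: MeasurementSet, predicted: MeasurementSet
) -> ATReport:
    """Per-ROI agreement indices between two normalized measurement sets."""
    if not (observed.normalized and predicted.normalized):
        raise ValidationError("both measurement sets must be normalized")
    if observed.schedule.times_h != predicted.schedule.times_h:
        raise ValidationError("measurement sets are on different scan schedules")
    at_st = at_index(observed.series[ROI_STOMACH], predicted.series[ROI_STOMACH])
    at_th = at_index(observed.series[ROI_THYROID], predicted.series[ROI_THYROID])
    at_bfwb = at_index(observed.series[ROI_BODY], predicted.series[ROI_BODY])
    return ATReport(
        at_st=at_st,
        at_th=at_th,
        at_bfwb=at_bfwb,
        at_total=at_total(at_st, at_th, at_bfwb),
        n=observed.schedule.n_scans,
    )
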