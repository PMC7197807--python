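"""Readers and writers for the measurement CSV and parameter/result JSON.

Measurement CSV dialect: comma-separated, UTF-8, mandatory header
``patient_id,time_h,roi,value_counts_per_pixel_per_s``, one row per
(patient, time, ROI). Recognised ROI labels are St, Th, BFWB, BKG, and
Bl; bladder rows are accepted on input and dropped (the bladder is not
part of the fitted observation model).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import CohortSummary, FitResult, SUMMARY_PARAMETERS
from .model_core import (
    BiokineticParameters,
    BiologicalHalfLives,
    BranchingRatios,
    PhysicalDecay,
    ValidationError,
)
from .observation import (
    MeasurementSet,
    ROI_LABELS,
    ScanSchedule,
)

__all__ = [
    "ParseError",
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "params_to_dict",
    "params_from_dict",
    "read_parameters",
    "write_parameters",
    "write_results",
    "read_summary",
]

MEASUREMENT_COLUMNS = ("patient_id", "time_h", "roi", "value_counts_per_pixel_per_s")
_KNOWN_ROIS = ROI_LABELS + ("BKG", "Bl")


class ParseError(ValueError):
    """The measurement file violates the CSV contract."""


def read_measurements(path) -> list[MeasurementSet]:
    """Parse a measurement CSV into one :class:`MeasurementSet` per patient.

    BKG rows are attached as the background series for later subtraction;
    each of St/Th/BFWB must cover exactly the patient's scan schedule.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, dtype={"patient_id": str, "roi": str}, float_precision="round_trip"
    )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    values = pd.to_numeric(frame["value_counts_per_pixel_per_s"], errors="coerce")
    times = pd.to_numeric(frame["time_h"], errors="coerce")
    bad = frame.index[values.isna() | times.isna()]
    if len(bad):
        raise ParseError(f"{path}: non-numeric value on line {bad[0] + 2}")
    frame = frame.assign(time_h=times, value_counts_per_pixel_per_s=values)

    unknown = frame.index[~frame["roi"].isin(_KNOWN_ROIS)]
    if len(unknown):
        raise ParseError(
            f"{path}: unknown ROI label {frame.loc[unknown[0], 'roi']!r} "
            f"on line {unknown[0] + 2}"
        )
    duplicated = frame.duplicated(subset=["patient_id", "time_h", "roi"], keep=False)
    if duplicated.any():
        line = frame.index[duplicated][0] + 2
        raise ParseError(f"{path}: duplicate (patient, time, roi) row on line {line}")

    frame = frame[frame["roi"] != "Bl"]
    measurements = []
    for patient_id in frame["patient_id"].drop_duplicates():
        block = frame[frame["patient_id"] == patient_id]
        schedule_times = tuple(sorted(block["time_h"].unique()))
        try:
            schedule = ScanSchedule(schedule_times)
        except ValidationError as exc:
            raise ParseError(f"{path}: patient {patient_id}: {exc}") from exc
        series = {}
        background = None
        for roi in block["roi"].drop_duplicates():
            sub = block[block["roi"] == roi].sort_values("time_h")
            roi_times = tuple(sub["time_h"])
            if roi_times != schedule_times:
                raise ParseError(
                    f"{path}: patient {patient_id} ROI {roi} covers times "
                    f"{roi_times}, expected {schedule_times}"
                )
            vals = sub["value_counts_per_pixel_per_s"].to_numpy(dtype=float)
            if roi == "BKG":
                background = vals
            else:
                series[roi] = vals
        try:
            measurements.append(
                MeasurementSet(
                    patient_id=patient_id,
                    schedule=schedule,
                    series=series,
                    normalized=False,
                    background=background,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: patient {patient_id}: {exc}") from exc
    return measurements


def write_measurements(measurements, path) -> None:
    """Write measurement sets to CSV, round-trip exact and deterministic."""
    path = Path(path)
    rows = []
    for ms in measurements:
        labels = list(ROI_LABELS) + (["BKG"] if ms.background is not None else [])
        for roi in labels:
            vals = ms.background if roi == "BKG" else ms.series[roi]
            for t, v in zip(ms.schedule.times_h, vals):
                rows.append((ms.patient_id, repr(float(t)), roi, repr(float(v))))
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(MEASUREMENT_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


def params_to_dict(params: BiokineticParameters) -> dict:
    return {
        "half_lives": {
            "stomach_h": params.half_lives.stomach_h,
            "bodyfluid_h": params.half_lives.bodyfluid_h,
            "thyroid_h": params.half_lives.thyroid_h,
            "wholebody_h": params.half_lives.wholebody_h,
        },
        "branching": {
            "i12": params.branching.i12,
            "i23": params.branching.i23,
            "i25": params.branching.i25,
            "i34": params.branching.i34,
            "i42": params.branching.i42,
            "i45": params.branching.i45,
        },
        "physical_half_life_h": params.physical.half_life_h,
    }


def params_from_dict(payload: dict) -> BiokineticParameters:
    try:
        return BiokineticParameters(
            half_lives=BiologicalHalfLives(**payload["half_lives"]),
            branching=BranchingRatios(**payload["branching"]),
            physical=PhysicalDecay(payload["physical_half_life_h"]),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed parameter payload: {exc}") from exc


def read_parameters(path) -> BiokineticParameters:
    with Path(path).open(encoding="utf-8") as fh:
        return params_from_dict(json.load(fh))


def write_parameters(params: BiokineticParameters, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(params_to_dict(params), indent=2) + "\n", "utf-8")


def _fit_result_to_dict(result: FitResult) -> dict:
    return {
        "patient_id": result.patient_id,
        "estimate": params_to_dict(result.estimate),
        "at": {
            "at_st": result.at_report.at_st,
            "at_th": result.at_report.at_th,
            "at_bfwb": result.at_report.at_bfwb,
            "at_total": result.at_report.at_total,
            "n": result.at_report.n,
        },
        "objective": result.objective,
        "converged": result.converged,
        "n_evaluations": result.n_evaluations,
    }


def write_results(results, summary: CohortSummary, outdir) -> dict[str, Path]:
    """Write per-patient JSON, a cohort CSV, and a summary JSON.

    The cohort CSV carries one data row per patient plus an ``Average``
    row holding the cohort means.
    """
    results = list(results)
    if not results:
        raise ValidationError("write_results requires a non-empty result list")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    for result in results:
        p = outdir / f"fit_{result.patient_id}.json"
        p.write_text(json.dumps(_fit_result_to_dict(result), indent=2) + "\n", "utf-8")
        written[f"fit_{result.patient_id}"] = p

    columns = [
        "patient_id", "t_stomach_h", "t_bfwb_h", "t_thyroid_h", "i23",
        "at_st", "at_th", "at_bfwb", "at_total",
    ]
    rows = []
    for result in results:
        free = result.free_values
        rows.append(
            [result.patient_id]
            + [free[k] for k in ("t_stomach_h", "t_bfwb_h", "t_thyroid_h", "i23")]
            + [
                result.at_report.at_st,
                result.at_report.at_th,
                result.at_report.at_bfwb,
                result.at_report.at_total,
            ]
        )
    rows.append(
        ["Average"]
        + [summary.means[k] for k in ("t_stomach_h", "t_bfwb_h", "t_thyroid_h", "i23")]
        + [np.nan] * 4
    )
    cohort_path = outdir / "cohort.csv"
    pd.DataFrame(rows, columns=columns).to_csv(
        cohort_path, index=False, float_format="%.6g"
    )
    written["cohort"] = cohort_path

    summary_payload = {
        "n_patients": summary.n_patients,
        "means": summary.means,
        "sds": summary.sds,
        "rounded": summary.rounded(),
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary_payload, indent=2) + "\n", "utf-8")
    written["summary"] = summary_path
    return written


def read_summary(path) -> CohortSummary:
    """Inverse of the summary JSON written by :func:`write_results`."""
    with Path(path).open(encoding="utf-8") as fh:
        payload = json.load(fh)
    sds = payload["sds"]
    return CohortSummary(
        n_patients=payload["n_patients"],
        means={k: float(v) for k, v in payload["means"].items()},
        sds=None if sds is None else {k: float(v) for k, v in sds.items()},
    )
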