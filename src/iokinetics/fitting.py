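"""Per-patient parameter estimation and cohort summarization.

The inverse problem has four free parameters: the stomach half-life, one
shared body-fluid/whole-body half-life, the thyroid half-life, and the
body-fluid-to-thyroid branching fraction i23 (i25 follows as 1 - i23).
The objective is the total agreement index between the normalized data
and the normalized model projection. Estimation is a bounded coarse grid
search followed by derivative-free local refinement, which is fully
deterministic for a given configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model_core import (
    BiokineticParameters,
    I131_HALF_LIFE_H,
    ValidationError,
    patient_parameters,
    solve_trajectory,
)
from .observation import (
    ATReport,
    MeasurementSet,
    ROI_LABELS,
    compute_at_report,
    normalize_dataset,
    project_observables,
)

__all__ = [
    "FitError",
    "FitConfig",
    "FitResult",
    "CohortSummary",
    "FREE_PARAMETERS",
    "fit_patient",
    "summarize_cohort",
]

#: Names and order of the free parameters of the inverse problem.
FREE_PARAMETERS = ("t_stomach_h", "t_bfwb_h", "t_thyroid_h", "i23")

#: Parameters reported in cohort summaries (i25 is derived from i23).
SUMMARY_PARAMETERS = FREE_PARAMETERS + ("i25",)

_DEFAULT_BOUNDS = {
    "t_stomach_h": (0.05, 5.0),
    "t_bfwb_h": (1.0, 100.0),
    "t_thyroid_h": (5.0, 500.0),
    "i23": (0.0, 1.0),
}

_DEFAULT_GRID_POINTS = {
    "t_stomach_h": 8,
    "t_bfwb_h": 8,
    "t_thyroid_h": 8,
    "i23": 6,
}

#: Reporting precision (decimal places) per summarized parameter.
_REPORT_DECIMALS = {
    "t_stomach_h": 2,
    "t_bfwb_h": 1,
    "t_thyroid_h": 1,
    "i23": 2,
    "i25": 2,
}


class FitError(RuntimeError):
    """The objective could not be evaluated or minimized."""


@dataclass(frozen=True)
class FitConfig:
    """Bounds, grid resolution, and refinement settings for one fit."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    grid_points: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GRID_POINTS)
    )
    physical_half_life_h: float = I131_HALF_LIFE_H
    n_refinement_starts: int = 3
    xatol: float = 1e-9
    fatol: float = 1e-13
    max_iterations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in FREE_PARAMETERS:
            if name not in self.bounds:
                raise ValidationError(f"bounds missing for parameter {name}")
            low, high = self.bounds[name]
            if not (low < high):
                raise ValidationError(f"bounds for {name} must satisfy low < high")
            if self.grid_points.get(name, 0) < 2:
                raise ValidationError(f"grid_points for {name} must be >= 2")
        if self.n_refinement_starts < 1:
            raise ValidationError("n_refinement_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Estimated kinetics with diagnostics for one patient."""

    patient_id: str
    estimate: BiokineticParameters
    at_report: ATReport
    objective: float
    converged: bool
    n_evaluations: int

    def __post_init__(self) -> None:
        if abs(self.objective - self.at_report.at_total) > 1e-10:
            raise ValidationError(
                "objective inconsistent with the recomputed total agreement index"
            )

    @property
    def free_values(self) -> dict[str, float]:
        return {
            "t_stomach_h": self.estimate.half_lives.stomach_h,
            "t_bfwb_h": self.estimate.half_lives.bodyfluid_h,
            "t_thyroid_h": self.estimate.half_lives.thyroid_h,
            "i23": self.estimate.branching.i23,
            "i25": self.estimate.branching.i25,
        }


@dataclass(frozen=True)
class CohortSummary:
    """Mean and sample standard deviation per parameter across patients."""

    n_patients: int
    means: dict[str, float]
    sds: dict[str, float] | None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("summary requires at least one patient")
        if self.n_patients < 2 and self.sds is not None:
            raise ValidationError("sample SD is undefined for a single patient")
        if self.sds is not None and any(v < 0 for v in self.sds.values()):
            raise ValidationError("standard deviations must be >= 0")

    def rounded(self) -> dict[str, dict[str, float]]:
        """Means/SDs rounded to reporting precision."""
        out = {
            "means": {
                k: round(v, _REPORT_DECIMALS[k]) for k, v in self.means.items()
            }
        }
        if self.sds is not None:
            out["sds"] = {
                k: round(v, _REPORT_DECIMALS[k]) for k, v in self.sds.items()
            }
        return out


def _validate_fit_data(data: MeasurementSet) -> None:
    if not data.normalized:
        raise ValidationError("fit_patient requires normalized measurements")
    missing = [roi for roi in ROI_LABELS if roi not in data.series]
    if missing:
        raise ValidationError(f"missing ROI series: {missing}")


def _make_objective(data: MeasurementSet, config: FitConfig):
    times = np.asarray(data.schedule.times_h)
    q0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    counter = {"n": 0}

    def objective(x) -> float:
        counter["n"] += 1
        t_st, t_bfwb, t_th, i23 = x
        try:
            params = patient_parameters(
                t_st, t_bfwb, t_th, i23, config.physical_half_life_h
            )
        except ValueError:
            return math.inf
        traj = solve_trajectory(params, q0, times)
        predicted = normalize_dataset(
            project_observables(traj, data.schedule, patient_id=data.patient_id)
        )
        return compute_at_report(data, predicted).at_total

    return objective, counter


def _grid_axes(config: FitConfig) -> list[np.ndarray]:
    axes = []
    for name in FREE_PARAMETERS:
        low, high = config.bounds[name]
        n = config.grid_points[name]
        if name == "i23":
            axes.append(np.linspace(low, high, n))
        else:
            axes.append(np.geomspace(low, high, n))
    return axes


def fit_patient(data: MeasurementSet, config: FitConfig | None = None) -> FitResult:
    """Estimate the four free parameters minimizing the total agreement index.

    A coarse bounded grid (log-spaced in the half-lives, linear in i23)
    locates candidate basins; Nelder-Mead refinement is started from the
    best grid points. Grid ties are broken toward the smallest thyroid,
    then smallest body-fluid half-life, making the result deterministic.
    """
    if config is None:
        config = FitConfig()
    _validate_fit_data(data)
    objective, counter = _make_objective(data, config)

    axes = _grid_axes(config)
    candidates = []
    for t_st in axes[0]:
        for t_bfwb in axes[1]:
            for t_th in axes[2]:
                for i23 in axes[3]:
                    x = (t_st, t_bfwb, t_th, i23)
                    candidates.append((objective(x), t_th, t_bfwb, x))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best_grid_value = candidates[0][0]
    if not math.isfinite(best_grid_value):
        raise FitError("objective is non-finite over the entire search grid")

    bounds = [config.bounds[name] for name in FREE_PARAMETERS]
    best_x = np.asarray(candidates[0][3])
    best_value = best_grid_value
    converged = False
    for _, _, _, x0 in candidates[: config.n_refinement_starts]:
        result = minimize(
            objective,
            np.asarray(x0),
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxiter": config.max_iterations,
                "maxfev": 4 * config.max_iterations,
            },
        )
        if result.fun < best_value:
            best_value = float(result.fun)
            best_x = np.asarray(result.x)
            converged = bool(result.success)

    estimate = patient_parameters(*best_x, config.physical_half_life_h)
    q0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    predicted = normalize_dataset(
        project_observables(
            solve_trajectory(estimate, q0, np.asarray(data.schedule.times_h)),
            data.schedule,
            patient_id=data.patient_id,
        )
    )
    at_report = compute_at_report(data, predicted)
    return FitResult(
        patient_id=data.patient_id,
        estimate=estimate,
        at_report=at_report,
        objective=at_report.at_total,
        converged=converged,
        n_evaluations=counter["n"],
    )


def _extract_values(item) -> dict[str, float]:
    if isinstance(item, FitResult):
        return item.free_values
    if isinstance(item, BiokineticParameters):
        return {
            "t_stomach_h": item.half_lives.stomach_h,
            "t_bfwb_h": item.half_lives.bodyfluid_h,
            "t_thyroid_h": item.half_lives.thyroid_h,
            "i23": item.branching.i23,
            "i25": item.branching.i25,
        }
    raise ValidationError(
        f"cannot summarize item of type {type(item).__name__}"
    )


def summarize_cohort(results) -> CohortSummary:
    """Arithmetic mean and sample SD (n-1 denominator) per parameter.

    Accepts :class:`FitResult` objects or bare :class:`BiokineticParameters`.
    SDs are reported as absent for a single-patient cohort.
    """
    results = list(results)
    if not results:
        raise ValidationError("cannot summarize an empty cohort")
    table = {name: [] for name in SUMMARY_PARAMETERS}
    for item in results:
        values = _extract_values(item)
        for name in SUMMARY_PARAMETERS:
            table[name].append(values[name])
    n = len(results)
    means = {name: float(np.mean(v)) for name, v in table.items()}
    sds = None
    if n >= 2:
        sds = {name: float(np.std(v, ddof=1)) for name, v in table.items()}
    return CohortSummary(n_patients=n, means=means, sds=sds)
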