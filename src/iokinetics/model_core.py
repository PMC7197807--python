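"""Linear five-compartment kinetics of orally administered radioiodine.

The body is modelled as a chain stomach -> body fluid -> thyroid -> whole
body, with a feedback path from the whole body back to the body fluid and
terminal losses from body fluid and whole body into an excretion pool.
All transfers are first order; physical decay acts on every compartment
simultaneously. Activities are expressed as fractions of the administered
activity, which starts entirely in the stomach.

Compartment indices are fixed throughout the package:
0 stomach, 1 body fluid, 2 thyroid, 3 whole body, 4 excretion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DomainError",
    "ValidationError",
    "PhysicalDecay",
    "BranchingRatios",
    "BiologicalHalfLives",
    "BiokineticParameters",
    "Trajectory",
    "decay_constant",
    "build_rate_matrix",
    "solve_trajectory",
    "solve_trajectory_rk4",
    "effective_half_life",
    "patient_parameters",
    "I131_HALF_LIFE_H",
    "REFERENCE_ADULT",
    "PATIENT_PARAMETER_ROWS",
    "PATIENT_PARAMETER_SETS",
    "AVERAGE_PATIENT",
    "STOMACH",
    "BODY_FLUID",
    "THYROID",
    "WHOLE_BODY",
    "EXCRETION",
]

LN2 = math.log(2.0)

#: Default physical half-life of I-131 in hours (8.02 days).
I131_HALF_LIFE_H = 192.5

N_COMPARTMENTS = 5
STOMACH, BODY_FLUID, THYROID, WHOLE_BODY, EXCRETION = range(N_COMPARTMENTS)


class DomainError(ValueError):
    """A scalar argument is outside its mathematical domain."""


class ValidationError(ValueError):
    """A structured input violates a type invariant or precondition."""


def decay_constant(half_life_h: float, branching: float = 1.0) -> float:
    """Transfer rate ``branching * ln2 / half_life_h`` in h^-1.

    Parameters
    ----------
    half_life_h
        Biological half-life of the source compartment, hours, > 0.
    branching
        Fraction of the compartment outflow routed along this path,
        in [0, 1].
    """
    if not (half_life_h > 0 and math.isfinite(half_life_h)):
        raise DomainError(f"half-life must be positive and finite, got {half_life_h}")
    if not (0.0 <= branching <= 1.0):
        raise DomainError(f"branching ratio must lie in [0, 1], got {branching}")
    return branching * LN2 / half_life_h


def effective_half_life(physical_h: float, biological_h: float) -> float:
    """Harmonic combination ``1 / (1/physical + 1/biological)`` in hours."""
    if not (physical_h > 0 and math.isfinite(physical_h)):
        raise DomainError(f"physical half-life must be positive, got {physical_h}")
    if not (biological_h > 0 and math.isfinite(biological_h)):
        raise DomainError(f"biological half-life must be positive, got {biological_h}")
    return 1.0 / (1.0 / physical_h + 1.0 / biological_h)


@dataclass(frozen=True)
class PhysicalDecay:
    """Physical decay of the radionuclide, identical in every compartment."""

    half_life_h: float = I131_HALF_LIFE_H

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0 and math.isfinite(self.half_life_h)):
            raise ValidationError(
                f"physical half-life must be positive and finite, got {self.half_life_h}"
            )

    @property
    def lambda_p(self) -> float:
        """Decay constant in h^-1."""
        return LN2 / self.half_life_h


@dataclass(frozen=True)
class BranchingRatios:
    """Outflow split fractions between compartments.

    ``i12`` (stomach -> body fluid) and ``i34`` (thyroid -> whole body)
    are structurally 1: each of those compartments has a single outflow.
    Body-fluid outflow splits into thyroid (``i23``) and excretion
    (``i25``); whole-body outflow splits into body fluid (``i42``) and
    excretion (``i45``). Each split must sum to 1.
    """

    i12: float = 1.0
    i23: float = 0.21
    i25: float = 0.79
    i34: float = 1.0
    i42: float = 0.9
    i45: float = 0.1

    _SPLIT_TOL = 1e-9

    def __post_init__(self) -> None:
        for name in ("i12", "i23", "i25", "i34", "i42", "i45"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.i12 != 1.0:
            raise ValidationError(f"i12 is structurally 1, got {self.i12}")
        if self.i34 != 1.0:
            raise ValidationError(f"i34 is structurally 1, got {self.i34}")
        if abs(self.i23 + self.i25 - 1.0) > self._SPLIT_TOL:
            raise ValidationError(
                f"i23 + i25 must equal 1, got {self.i23} + {self.i25}"
            )
        if abs(self.i42 + self.i45 - 1.0) > self._SPLIT_TOL:
            raise ValidationError(
                f"i42 + i45 must equal 1, got {self.i42} + {self.i45}"
            )


@dataclass(frozen=True)
class BiologicalHalfLives:
    """Biological (decay-free) half-lives of the four transfer compartments, hours."""

    stomach_h: float
    bodyfluid_h: float
    thyroid_h: float
    wholebody_h: float

    def __post_init__(self) -> None:
        for name in ("stomach_h", "bodyfluid_h", "thyroid_h", "wholebody_h"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValidationError(
                    f"{name} must be positive and finite, got {value}"
                )


@dataclass(frozen=True)
class BiokineticParameters:
    """Complete parameterisation of the five-compartment system."""

    half_lives: BiologicalHalfLives
    branching: BranchingRatios
    physical: PhysicalDecay

    @property
    def lambda_12(self) -> float:
        return decay_constant(self.half_lives.stomach_h, self.branching.i12)

    @property
    def lambda_23(self) -> float:
        return decay_constant(self.half_lives.bodyfluid_h, self.branching.i23)

    @property
    def lambda_25(self) -> float:
        return decay_constant(self.half_lives.bodyfluid_h, self.branching.i25)

    @property
    def lambda_34(self) -> float:
        return decay_constant(self.half_lives.thyroid_h, self.branching.i34)

    @property
    def lambda_42(self) -> float:
        return decay_constant(self.half_lives.wholebody_h, self.branching.i42)

    @property
    def lambda_45(self) -> float:
        return decay_constant(self.half_lives.wholebody_h, self.branching.i45)


def patient_parameters(
    t_stomach_h: float,
    t_bfwb_h: float,
    t_thyroid_h: float,
    i23: float,
    physical_half_life_h: float = I131_HALF_LIFE_H,
) -> BiokineticParameters:
    """Build parameters in the reduced patient parameterisation.

    Body-fluid and whole-body half-lives share a single value, and the
    whole-body split is fixed at i42 = 0.9 / i45 = 0.1, matching the
    structure in which patient kinetics are reported and fitted.
    """
    return BiokineticParameters(
        half_lives=BiologicalHalfLives(
            stomach_h=t_stomach_h,
            bodyfluid_h=t_bfwb_h,
            thyroid_h=t_thyroid_h,
            wholebody_h=t_bfwb_h,
        ),
        branching=BranchingRatios(i23=i23, i25=1.0 - i23),
        physical=PhysicalDecay(physical_half_life_h),
    )


#: Reference healthy-adult kinetics (distinct body-fluid and whole-body
#: half-lives, i23 = 0.3).
REFERENCE_ADULT = BiokineticParameters(
    half_lives=BiologicalHalfLives(
        stomach_h=0.696, bodyfluid_h=6.0, thyroid_h=1920.0, wholebody_h=288.0
    ),
    branching=BranchingRatios(i23=0.30, i25=0.70),
    physical=PhysicalDecay(I131_HALF_LIFE_H),
)

#: Per-patient reduced parameters (t_stomach_h, t_bfwb_h, t_thyroid_h, i23)
#: for the nine-patient ablation cohort shipped as the package default.
PATIENT_PARAMETER_ROWS: tuple[tuple[float, float, float, float], ...] = (
    (0.50, 15.0, 35.0, 0.18),
    (0.30, 14.0, 50.0, 0.50),
    (0.30, 10.0, 40.0, 0.30),
    (0.33, 11.0, 40.0, 0.15),
    (0.35, 12.0, 50.0, 0.04),
    (0.60, 15.0, 40.0, 0.30),
    (0.45, 13.0, 45.0, 0.18),
    (0.70, 12.5, 40.0, 0.15),
    (1.30, 11.0, 45.0, 0.08),
)

PATIENT_PARAMETER_SETS: tuple[BiokineticParameters, ...] = tuple(
    patient_parameters(*row) for row in PATIENT_PARAMETER_ROWS
)

#: Cohort-average patient kinetics (rounded means of the nine rows).
AVERAGE_PATIENT = patient_parameters(0.54, 12.6, 42.8, 0.21)


@dataclass(frozen=True)
class Trajectory:
    """Compartment activity fractions evaluated on a time grid.

    ``q`` has shape ``(len(times_h), 5)``; column order is stomach, body
    fluid, thyroid, whole body, excretion.
    """

    times_h: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if times.ndim != 1:
            raise ValidationError("times_h must be one-dimensional")
        if np.any(times < 0):
            raise ValidationError("times must be non-negative")
        if np.any(np.diff(times) < 0):
            raise ValidationError("times must be sorted ascending")
        if q.shape != (times.size, N_COMPARTMENTS):
            raise ValidationError(
                f"q must have shape ({times.size}, {N_COMPARTMENTS}), got {q.shape}"
            )
        if np.any(q < 0):
            raise ValidationError("compartment activities must be non-negative")
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "q", q)

    @property
    def stomach(self) -> np.ndarray:
        return self.q[:, STOMACH]

    @property
    def body_fluid(self) -> np.ndarray:
        return self.q[:, BODY_FLUID]

    @property
    def thyroid(self) -> np.ndarray:
        return self.q[:, THYROID]

    @property
    def whole_body(self) -> np.ndarray:
        return self.q[:, WHOLE_BODY]

    @property
    def excretion(self) -> np.ndarray:
        return self.q[:, EXCRETION]


def build_rate_matrix(params: BiokineticParameters) -> np.ndarray:
    """Generator matrix ``A`` of the linear system ``dq/dt = A q``.

    ``A = B - lambda_p * I`` where ``B`` holds the biological transfers
    and has zero column sums (biological flows conserve activity; only
    physical decay removes it from the closed five-compartment system).
    """
    lp = params.physical.lambda_p
    l12, l23, l25 = params.lambda_12, params.lambda_23, params.lambda_25
    l34, l42, l45 = params.lambda_34, params.lambda_42, params.lambda_45

    B = np.zeros((N_COMPARTMENTS, N_COMPARTMENTS))
    B[STOMACH, STOMACH] = -l12
    B[BODY_FLUID, STOMACH] = l12
    B[BODY_FLUID, BODY_FLUID] = -(l23 + l25)
    B[BODY_FLUID, WHOLE_BODY] = l42
    B[THYROID, BODY_FLUID] = l23
    B[THYROID, THYROID] = -l34
    B[WHOLE_BODY, THYROID] = l34
    B[WHOLE_BODY, WHOLE_BODY] = -(l42 + l45)
    B[EXCRETION, BODY_FLUID] = l25
    B[EXCRETION, WHOLE_BODY] = l45
    return B - lp * np.eye(N_COMPARTMENTS)


def _validate_initial_state(q0) -> np.ndarray:
    q0 = np.asarray(q0, dtype=float)
    if q0.shape != (N_COMPARTMENTS,):
        raise ValidationError(f"q0 must have shape ({N_COMPARTMENTS},), got {q0.shape}")
    if np.any(q0 < 0):
        raise ValidationError("initial activities must be non-negative")
    return q0


def _validate_times(times_h) -> np.ndarray:
    times = np.asarray(times_h, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("times_h must be a non-empty one-dimensional sequence")
    if np.any(times < 0):
        raise ValidationError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValidationError("times must be sorted ascending")
    return times


def _clamp_roundoff_negatives(q: np.ndarray) -> np.ndarray:
    # expm of a Metzler matrix is entrywise non-negative; any negative
    # entries here are round-off at the 1e-16 scale, not model output.
    tiny = q < 0
    if np.any(q[tiny] < -1e-12):
        raise RuntimeError("solver produced substantially negative activity")
    q[tiny] = 0.0
    return q


def solve_trajectory(
    params: BiokineticParameters, q0, times_h
) -> Trajectory:
    """Exact solution of the constant-coefficient system via matrix exponential.

    Propagates between consecutive requested times with scaling-and-squaring
    matrix exponentials, which remains correct under coincident eigenvalues
    (e.g. equal body-fluid and whole-body half-lives).
    """
    q0 = _validate_initial_state(q0)
    times = _validate_times(times_h)
    A = build_rate_matrix(params)

    deltas = np.diff(np.concatenate(([0.0], times)))
    # one batched expm call for all propagators
    propagators = expm(A[np.newaxis, :, :] * deltas[:, np.newaxis, np.newaxis])
    q = np.empty((times.size, N_COMPARTMENTS))
    state = q0
    for k in range(times.size):
        state = propagators[k] @ state
        q[k] = state
    return Trajectory(times_h=times, q=_clamp_roundoff_negatives(q))


def solve_trajectory_rk4(
    params: BiokineticParameters, q0, times_h, step_h: float = 0.001
) -> Trajectory:
    """Classical fixed-step fourth-order integration of the same system.

    Serves as an independent numerical oracle for :func:`solve_trajectory`.
    Each inter-sample interval is subdivided into ``ceil(delta / step_h)``
    equal steps so every requested time is hit exactly.
    """
    q0 = _validate_initial_state(q0)
    times = _validate_times(times_h)
    if not (step_h > 0):
        raise ValidationError(f"step_h must be positive, got {step_h}")
    gaps = np.diff(np.concatenate(([0.0], times)))
    positive_gaps = gaps[gaps > 0]
    if positive_gaps.size and step_h > positive_gaps.min() + 1e-12:
        raise ValidationError(
            f"step_h={step_h} exceeds the smallest inter-sample spacing "
            f"{positive_gaps.min()}"
        )
    A = build_rate_matrix(params)

    q = np.empty((times.size, N_COMPARTMENTS))
    state = q0.copy()
    t_prev = 0.0
    for k, t in enumerate(times):
        delta = t - t_prev
        if delta > 0:
            n_steps = max(1, int(math.ceil(delta / step_h - 1e-12)))
            h = delta / n_steps
            for _ in range(n_steps):
                k1 = A @ state
                k2 = A @ (state + 0.5 * h * k1)
                k3 = A @ (state + 0.5 * h * k2)
                k4 = A @ (state + h * k3)
                state = state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        q[k] = state
        t_prev = t
    return Trajectory(times_h=times, q=_clamp_roundoff_negatives(q))
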