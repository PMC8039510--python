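"""Glucose minimal model under measured-insulin forcing.

The model describes glucose disappearance after an intravenous glucose bolus
(IVGTT, optionally insulin-modified) with four individual parameters:

* ``GEZI`` — glucose effectiveness at zero insulin (1/min),
* ``SI``   — insulin sensitivity (1/min per pmol/L),
* ``p2``   — rate constant of the remote insulin-action compartment (1/min),
* ``V``    — apparent glucose distribution volume (L).

Plasma insulin is not modelled mechanistically: the measured concentrations
are linearly interpolated and drive the remote-action state X(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np

from . import _core

MW_GLUCOSE = 180.16  # g/mol, anhydrous D-glucose

#: glucose observations earlier than this (min) are excluded from fitting:
#: single-compartment kinetics do not represent the initial mixing phase.
EARLY_CUTOFF_MIN = 5.0

#: minimum number of glucose observations a subject must retain after the
#: early-sample filter to be fittable.
MIN_OBSERVATIONS = 4

DEFAULT_DT_MAX = 0.5  # min, maximum RK4 sub-step of the simulator

PARAM_NAMES = ("GEZI", "SI", "p2", "V")


class TestType(str, Enum):
    IVGTT = "IVGTT"
    IM_IVGTT = "IM-IVGTT"


class DataInsufficiencyError(ValueError):
    """A subject does not retain enough observations to be fitted."""


class SimulationError(RuntimeError):
    """The ODE integrator failed to produce a finite, positive solution."""


@dataclass(frozen=True)
class InsulinForcing:
    """Measured insulin concentrations defining the forcing function I(t)."""

    times: np.ndarray          # min, strictly increasing
    concentrations: np.ndarray  # pmol/L, non-negative
    Ibasal: float              # pmol/L

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size < 2:
            raise ValueError("insulin forcing needs at least 2 points")
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("insulin times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("insulin concentrations must be non-negative")
        if self.Ibasal < 0:
            raise ValueError("Ibasal must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class MMParams:
    """Individual minimal-model parameter vector (all strictly positive)."""

    GEZI: float  # 1/min
    SI: float    # 1/min per pmol/L
    p2: float    # 1/min
    V: float     # L

    def __post_init__(self):
        for name in PARAM_NAMES:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.GEZI, self.SI, self.p2, self.V])

    @classmethod
    def from_array(cls, arr) -> "MMParams":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class SubjectData:
    """One subject's IVGTT record: dose, glucose series, insulin forcing."""

    subject_id: str
    test_type: TestType
    dose: float              # mmol at t=0
    obs_times: np.ndarray    # min
    obs_glucose: np.ndarray  # mmol/L
    forcing: InsulinForcing
    Gbasal: float            # mmol/L
    Ibasal: float            # pmol/L
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.obs_times, dtype=float)
        g = np.asarray(self.obs_glucose, dtype=float)
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.Gbasal <= 0:
            raise ValueError("Gbasal must be positive")
        if t.size != g.size:
            raise ValueError("obs_times and obs_glucose must have equal length")
        if t.size and (t.min() < 0 or t.max() > 360):
            raise ValueError("observation times must lie within [0, 360] min")
        if np.any(np.diff(t) < 0):
            raise ValueError("observation times must be non-decreasing")
        if np.any(g <= 0):
            raise ValueError("glucose observations must be positive")
        object.__setattr__(self, "obs_times", t)
        object.__setattr__(self, "obs_glucose", g)


def dose_to_mmol(dose_g_per_kg: float, weight: float) -> float:
    """Convert a weight-based glucose dose (g/kg) to mmol.

    The standard IVGTT bolus is 0.3 g/kg; with the molar mass of glucose
    180.16 g/mol this yields dose_g_per_kg * weight * 1000 / 180.16 mmol.
    """
    if dose_g_per_kg <= 0 or weight <= 0:
        raise ValueError("dose_g_per_kg and weight must be positive")
    return dose_g_per_kg * weight * 1000.0 / MW_GLUCOSE


def interpolate_insulin(forcing: InsulinForcing, t: float) -> float:
    """Evaluate I(t): linear between knots, constant outside the range."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(_core.interp_linear(forcing.times, forcing.concentrations, float(t)))


def simulate_glucose(params: MMParams, dose: float, Gbasal: float, Ibasal: float,
                     forcing: InsulinForcing, eval_times,
                     dt_max: float = DEFAULT_DT_MAX) -> np.ndarray:
    """Simulate the glucose concentration G(t) at ``eval_times``.

    X(t) is advanced with its per-segment closed form over the piecewise
    linear forcing; G(t) with bounded RK4 sub-steps (see ``popmm._core``).
    """
    te = np.asarray(eval_times, dtype=float)
    if te.ndim != 1 or te.size == 0:
        raise ValueError("eval_times must be a non-empty 1-D array")
    if np.any(np.diff(te) < 0) or te[0] < 0:
        raise ValueError("eval_times must be non-decreasing and non-negative")
    out = _core.simulate_mm(params.GEZI, params.SI, params.p2, params.V,
                            float(dose), float(Gbasal), float(Ibasal),
                            forcing.times, forcing.concentrations, te,
                            float(dt_max))
    if not np.all(np.isfinite(out)):
        raise SimulationError(
            f"glucose simulation failed (params={params}, dose={dose})")
    return out


def glucose_closed_form_constant_insulin(params: MMParams, dose: float,
                                         Gbasal: float, Ibasal: float,
                                         t) -> np.ndarray:
    """Analytic G(t) when I(t) == Ibasal for all t.

    Then X(t) stays at SI*Ibasal and the glucose equation collapses to a
    linear constant-coefficient ODE:

        G(t) = Gbasal + (Dose/V) * exp(-(GEZI + SI*Ibasal) * t)
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rate = params.GEZI + params.SI * Ibasal
    return Gbasal + (dose / params.V) * np.exp(-rate * t)


def simulate_glucose_bruteforce(params: MMParams, dose: float, Gbasal: float,
                                Ibasal: float, forcing: InsulinForcing,
                                eval_times, dt: float = 0.001) -> np.ndarray:
    """Fixed-step RK4 reference integration of the coupled (G, X) system.

    A deliberately simple, fully numeric path (insulin re-interpolated at
    every stage) kept as an independent oracle for the production simulator.
    """
    te = np.asarray(eval_times, dtype=float)
    return _core.simulate_mm_fixed_step(
        params.GEZI, params.SI, params.p2, params.V, float(dose),
        float(Gbasal), float(Ibasal), forcing.times, forcing.concentrations,
        te, float(dt))


def filter_early_samples(subject: SubjectData) -> SubjectData:
    """Drop glucose observations earlier than 5 min (boundary kept).

    The one-compartment model does not represent the initial mixing phase.
    The insulin forcing is left untouched.  Raises
    :class:`DataInsufficiencyError` when fewer than 4 observations remain.
    """
    keep = subject.obs_times >= EARLY_CUTOFF_MIN
    if keep.sum() < MIN_OBSERVATIONS:
        raise DataInsufficiencyError(
            f"subject {subject.subject_id}: only {int(keep.sum())} glucose "
            f"observations at t >= {EARLY_CUTOFF_MIN} min "
            f"(minimum {MIN_OBSERVATIONS})")
    if keep.all():
        return subject
    return replace(subject, obs_times=subject.obs_times[keep],
                   obs_glucose=subject.obs_glucose[keep])
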