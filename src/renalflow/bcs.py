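"""Haemodynamic boundary conditions.

Steady boundary conditions are derived from pulsatile resting waveforms by
time-averaging over one heart cycle: a plug (uniform) inlet velocity from the
mean flow, and a lumped peripheral-resistance (or fixed-pressure) outlet that
represents the downstream renal microcirculation.  An outlet-pressure tuning
loop adjusts the outlet pressure until the solved flow matches a target
resting level, for workflows where the inlet is pressure- rather than
flow-driven.

Hyperaemic states are deliberately not modelled; all defaults are resting
values.  SI units throughout (s, m^3/s, Pa, Pa*s/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Blood dynamic viscosity (Pa s) and density (kg/m^3) used throughout.
BLOOD_VISCOSITY = 0.0035
BLOOD_DENSITY = 1066.0

#: Generic resting renal values: mean inlet flow ~480 mL/min per kidney and a
#: mean distal arterial pressure of ~95 mmHg, representative of a healthy
#: resting state.
DEFAULT_MEAN_FLOW = 8.0e-6  # m^3/s
DEFAULT_MEAN_PRESSURE = 12_700.0  # Pa
DEFAULT_HEART_PERIOD = 0.8  # s


class BoundaryConditionError(ValueError):
    pass


class TuningError(RuntimeError):
    """Outlet-pressure tuning failed; carries the best iterate found."""

    def __init__(self, message: str, best_pressure: float, best_flow: float):
        super().__init__(message)
        self.best_pressure = best_pressure
        self.best_flow = best_flow


@dataclass(frozen=True)
class Waveform:
    """Sampled periodic signal over one heart cycle (flow or pressure)."""

    times: np.ndarray  # s, strictly increasing
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise BoundaryConditionError("times and values must be equal-length 1-D")
        if len(t) < 2:
            raise BoundaryConditionError("waveform needs at least 2 samples")
        if np.any(np.diff(t) <= 0.0):
            raise BoundaryConditionError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_csv(cls, path: str) -> "Waveform":
        data = np.loadtxt(path, delimiter=",", comments="#")
        return cls(times=data[:, 0], values=data[:, 1])

    def to_csv(self, path: str) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header="time_s,value",
        )


def generic_renal_flow_waveform(
    mean_flow: float = DEFAULT_MEAN_FLOW,
    period: float = DEFAULT_HEART_PERIOD,
    n_samples: int = 200,
) -> Waveform:
    """Synthetic resting renal-artery flow waveform with the given mean.

    A two-harmonic periodic shape (systolic peak, diastolic runoff) whose
    cycle average equals ``mean_flow`` exactly; a stand-in for subject-
    specific flow data when only the mean matters to the steady model.
    """
    t = np.linspace(0.0, period, n_samples)
    phase = 2.0 * np.pi * t / period
    shape = 1.0 + 0.45 * np.sin(phase) + 0.15 * np.sin(2.0 * phase + 0.5 * np.pi)
    return Waveform(times=t, values=mean_flow * shape)


def time_average(waveform: Waveform) -> float:
    """Cycle-averaged value: time-weighted (trapezoidal) mean, not a sample mean."""
    t, v = waveform.times, waveform.values
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def peripheral_resistance(mean_pressure_drop: float, mean_flow: float) -> float:
    """Lumped resistance: pressure drop to the capillary level over the flow."""
    if mean_flow <= 0.0:
        raise BoundaryConditionError(f"mean_flow must be > 0, got {mean_flow}")
    return mean_pressure_drop / mean_flow


def plug_inlet_velocity(flow_rate: float, inlet_area: float) -> float:
    """Uniform inlet speed U = Q / A (m/s), directed along the inward normal."""
    if inlet_area <= 0.0:
        raise BoundaryConditionError(f"inlet_area must be > 0, got {inlet_area}")
    if flow_rate < 0.0:
        raise BoundaryConditionError(f"flow_rate must be >= 0, got {flow_rate}")
    return flow_rate / inlet_area


@dataclass(frozen=True)
class Fluid:
    viscosity: float = BLOOD_VISCOSITY  # Pa s
    density: float = BLOOD_DENSITY  # kg/m^3

    def __post_init__(self):
        if self.viscosity <= 0.0 or self.density <= 0.0:
            raise BoundaryConditionError("viscosity and density must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class FlowCase:
    """Complete steady boundary-condition set for one simulation.

    Exactly one outlet mode is active: ``"resistance"`` imposes the outlet
    pressure P = reference_pressure + R * Q (updated with the solved flow),
    ``"fixed_pressure"`` imposes ``outlet_pressure`` directly.
    """

    fluid: Fluid = field(default_factory=Fluid)
    flow_rate: float = DEFAULT_MEAN_FLOW  # m^3/s, plug inlet
    outlet_mode: str = "resistance"
    resistance: float = DEFAULT_MEAN_PRESSURE / DEFAULT_MEAN_FLOW  # Pa s/m^3
    reference_pressure: float = 0.0  # Pa, distal reference for resistance mode
    outlet_pressure: float = DEFAULT_MEAN_PRESSURE  # Pa, fixed_pressure mode

    def __post_init__(self):
        if self.flow_rate < 0.0:
            raise BoundaryConditionError("flow_rate must be >= 0")
        if self.outlet_mode not in ("resistance", "fixed_pressure"):
            raise BoundaryConditionError(
                f"outlet_mode must be 'resistance' or 'fixed_pressure', "
                f"got {self.outlet_mode!r}"
            )

    def outlet_pressure_for(self, flow: float) -> float:
        if self.outlet_mode == "resistance":
            return self.reference_pressure + self.resistance * flow
        return self.outlet_pressure


@dataclass
class TuningResult:
    pressure: float  # Pa
    flow: float  # m^3/s
    iterations: int
    trajectory: list[tuple[float, float]]  # (pressure, flow) per evaluation


def tune_outlet_pressure(
    case_solver,
    target_flow: float,
    tolerance: float = 0.01,
    max_iterations: int = 20,
    initial_pressure: float = DEFAULT_MEAN_PRESSURE,
    pressure_step: float = 500.0,
) -> TuningResult:
    """Adjust the outlet pressure until the solved flow matches a target.

    ``case_solver`` maps an outlet pressure (Pa) to a solved inlet flow
    (m^3/s).  Root finding uses secant steps on f(p) = Q(p) - target with a
    bisection fallback once a sign-changing bracket is found, so a strictly
    monotone flow-pressure relation always converges.  Raises
    :class:`TuningError` (with the best iterate) if the relative flow
    mismatch is still above ``tolerance`` after ``max_iterations``
    evaluations.
    """
    if target_flow <= 0.0:
        raise BoundaryConditionError("target_flow must be > 0")
    trajectory: list[tuple[float, float]] = []
    bracket: list[tuple[float, float]] = []  # (p, f) with opposite-sign f

    def evaluate(p: float) -> float:
        q = case_solver(p)
        trajectory.append((p, q))
        return q - target_flow

    def _update_bracket(p: float, f: float) -> None:
        for pb, fb in bracket:
            if fb * f < 0.0:
                bracket[:] = [(pb, fb), (p, f)]
                return
        if not bracket or abs(f) < abs(bracket[-1][1]):
            bracket.append((p, f))
            del bracket[:-2]

    p0, p1 = initial_pressure, initial_pressure + pressure_step
    f0 = evaluate(p0)
    if abs(f0) <= tolerance * target_flow:
        return TuningResult(p0, f0 + target_flow, 1, trajectory)
    _update_bracket(p0, f0)
    f1 = evaluate(p1)
    p_prev, f_prev, p_cur, f_cur = p0, f0, p1, f1
    while len(trajectory) <= max_iterations:
        if abs(f_cur) <= tolerance * target_flow:
            return TuningResult(
                p_cur, f_cur + target_flow, len(trajectory), trajectory
            )
        _update_bracket(p_cur, f_cur)
        have_bracket = (
            len(bracket) == 2 and bracket[0][1] * bracket[1][1] < 0.0
        )
        if f_cur != f_prev:
            p_next = p_cur - f_cur * (p_cur - p_prev) / (f_cur - f_prev)
        else:
            p_next = None
        if have_bracket:
            lo, hi = sorted(b[0] for b in bracket)
            if p_next is None or not (lo < p_next < hi):
                p_next = 0.5 * (lo + hi)  # bisection fallback
        elif p_next is None:
            break  # flat response and no bracket: unreachable target
        p_prev, f_prev = p_cur, f_cur
        p_cur = p_next
        if len(trajectory) >= max_iterations:
            break
        f_cur = evaluate(p_cur)
    best = min(trajectory, key=lambda pq: abs(pq[1] - target_flow))
    raise TuningError(
        f"outlet-pressure tuning did not reach |Q - target|/target <= "
        f"{tolerance} within {max_iterations} evaluations "
        f"(best flow {best[1]:.4g} vs target {target_flow:.4g})",
        best_pressure=best[0],
        best_flow=best[1],
    )
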