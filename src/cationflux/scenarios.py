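"""Event-driven time-course simulation of the stimulus protocols.

The experiments start from starved cells in water.  A KCl addition raises the
external K+ and Cl- concentrations instantaneously (equimolar salt, the 3 ml
bath volume is treated as constant); the glucose addition is a switch that
turns on ATP production and activates the glucose-responsive phenomenological
coefficients.  Integration is piecewise between events with a stiff solver
(LSODA), restarting exactly at each event time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint, solve_ivp

from .model_core import (
    IONS,
    Model,
    ModelError,
    SystemState,
    rhs,
)
from .parameters import ParameterSet

__all__ = [
    "KCL_DOSES_MM",
    "StimulusEvent",
    "ScenarioSchedule",
    "Trajectory",
    "SimulationError",
    "apply_event",
    "simulate",
    "build_reference_scenarios",
]

#: the four KCl doses of the experimental design, mM
KCL_DOSES_MM = (0.01, 0.1, 1.0, 10.0)


class SimulationError(ModelError, RuntimeError):
    """Integrator failure, annotated with the time it occurred."""

    def __init__(self, message: str, time_reached: float = 0.0):
        super().__init__(message)
        self.time_reached = time_reached


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: KCl addition (amount in mM) or the glucose switch."""

    time: float  # s
    kind: str  # "kcl_addition" | "glucose"
    amount: float = 0.0  # mM, KCl only

    def __post_init__(self) -> None:
        if self.kind not in ("kcl_addition", "glucose"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind == "kcl_addition" and self.amount < 0:
            raise ValueError("KCl amount must be non-negative")


@dataclass(frozen=True)
class ScenarioSchedule:
    """Ordered stimulus events plus the simulated span and output grid step."""

    events: tuple[StimulusEvent, ...]
    span: float  # s
    output_step: float = 1.0  # s

    def __post_init__(self) -> None:
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.span):
            raise ValueError("event times must lie within the span")
        if self.span <= 0 or self.output_step <= 0:
            raise ValueError("span and output step must be positive")
        object.__setattr__(self, "events", events)

    def shifted(self, offset: float) -> "ScenarioSchedule":
        return ScenarioSchedule(
            tuple(StimulusEvent(e.time + offset, e.kind, e.amount) for e in self.events),
            span=self.span + offset,
            output_step=self.output_step,
        )


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: states plus fluxes and forces on the output grid.

    ``states`` has one row per grid time in the layout order of the parameter
    set; at an event time the recorded state is the post-event state.
    """

    params: ParameterSet
    times: np.ndarray  # (n,)
    states: np.ndarray  # (n, d)
    fluxes: np.ndarray  # (n, 5): J_H, J_K, J_Na, J_Cl, J_Ar (mol m^-2 s^-1)
    forces: np.ndarray  # (n, 5): X_H, X_K, X_Na, X_Cl, X_Ar
    events: tuple[StimulusEvent, ...]
    glucose_time: "float | None"

    @property
    def layout(self):
        return self.params.layout

    def column(self, name: str) -> np.ndarray:
        names = self.layout.names()
        return self.states[:, names.index(name)]

    def concentration(self, ion: str, side: str) -> np.ndarray:
        idx = self.layout.c_in(ion) if side == "in" else self.layout.c_out(ion)
        return self.states[:, idx]

    @property
    def delta_phi(self) -> np.ndarray:
        return self.states[:, self.layout.I_DPHI]

    @property
    def c_atp(self) -> np.ndarray:
        return self.states[:, self.layout.I_ATP]

    def flux(self, species: str) -> np.ndarray:
        order = ("H", "K", "Na", "Cl", "Ar")
        return self.fluxes[:, order.index(species)]

    def coefficient_series(self, a: str, b: str) -> np.ndarray:
        """Live value of L_ab on the grid (constant series for static entries)."""
        entry = self.params.matrix.get(a, b)
        if hasattr(entry, "init_value"):  # dynamic: stored in the state
            return self.states[:, self.layout.dynamic(a, b)]
        return np.full_like(self.times, float(entry))

    def state_at(self, t: float) -> SystemState:
        i = int(np.argmin(np.abs(self.times - t)))
        return SystemState(self.layout, self.states[i], t=float(self.times[i]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_s, variable, value, units."""
        unit_of = {"delta_phi": "V", "c_ATP": "mM"}
        rows = []
        for j, name in enumerate(self.layout.names()):
            units = unit_of.get(name, "mM" if name.startswith("c_") else "mol^2/(J m^2 s)")
            rows.append(pd.DataFrame({"time_s": self.times, "variable": name,
                                      "value": self.states[:, j], "units": units}))
        for j, sp in enumerate(("H", "K", "Na", "Cl", "Ar")):
            rows.append(pd.DataFrame({"time_s": self.times, "variable": f"J_{sp}",
                                      "value": self.fluxes[:, j], "units": "mol/(m^2 s)"}))
            rows.append(pd.DataFrame({"time_s": self.times, "variable": f"X_{sp}",
                                      "value": self.forces[:, j], "units": "J/(mol K)"}))
        return pd.concat(rows, ignore_index=True)

    def export(self, directory: "str | Path", condition: str = "") -> None:
        """Write the tidy CSV plus a JSON event log side-car."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        if condition:
            frame["condition"] = condition
        frame.to_csv(directory / "trajectory.csv", index=False)
        log = [{"time_s": e.time, "kind": e.kind, "amount_mM": e.amount} for e in self.events]
        (directory / "events.json").write_text(json.dumps(log, indent=1))


def apply_event(
    state: SystemState, event: StimulusEvent, model: Model
) -> tuple[SystemState, Model]:
    """Apply one stimulus instantaneously; returns the new state and model phase."""
    y = state.vector.copy()
    if event.kind == "kcl_addition":
        y[state.layout.c_out("K")] += event.amount
        y[state.layout.c_out("Cl")] += event.amount
        new_model = model
    elif event.kind == "glucose":
        new_model = model.with_glucose()
    else:  # pragma: no cover - guarded in StimulusEvent
        raise ValueError(f"unknown event kind {event.kind!r}")
    new_state = SystemState(state.layout, y, t=event.time)
    new_state.validate()
    return new_state, new_model


def _segment_grid(t0: float, t1: float, step: float, origin: float) -> np.ndarray:
    """Output grid points in (t0, t1] aligned to origin + k*step, plus t1."""
    k0 = np.ceil((t0 - origin) / step + 1e-9)
    pts = origin + step * np.arange(k0, np.floor((t1 - origin) / step + 1e-9) + 1)
    pts = pts[(pts > t0 + 1e-12) & (pts < t1 - 1e-12)]
    return np.concatenate([pts, [t1]])


def simulate(
    schedule: ScenarioSchedule,
    params: ParameterSet,
    initial: "SystemState | None" = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    buffering: str = "constant",
    t_start: float = 0.0,
) -> Trajectory:
    """Integrate the model over the schedule, restarting exactly at event times.

    Deterministic for fixed inputs and tolerances.  The recorded state at an
    event time is the post-event state.
    """
    state = params.initial_state() if initial is None else initial
    model = params.model(buffering=buffering)
    layout = params.layout

    times: list[np.ndarray] = [np.array([t_start])]
    states: list[np.ndarray] = [state.vector[None, :]]
    glucose_time = None

    boundaries = [t_start] + [e.time for e in schedule.events] + [schedule.span]
    y = state.vector.copy()
    for seg, (t0, t1) in enumerate(zip(boundaries, boundaries[1:])):
        if seg > 0:
            event = schedule.events[seg - 1]
            st, model = apply_event(SystemState(layout, y, t=t0), event, model)
            y = st.vector.copy()
            if event.kind == "glucose":
                glucose_time = event.time
            # re-record the event time with the post-event state
            times.append(np.array([t0]))
            states.append(y[None, :])
        if t1 <= t0:
            continue
        grid = _segment_grid(t0, t1, schedule.output_step, origin=t_start)
        if method == "LSODA":
            # odeint is the direct odepack LSODA interface (much lower overhead
            # than the generic solve_ivp wrapper for this stiff system)
            t_grid = np.concatenate([[t0], grid])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ODEintWarning)
                out, info = odeint(
                    rhs, y, t_grid, args=(model,), tfirst=True,
                    rtol=rtol, atol=atol, full_output=True, mxstep=100000,
                )
            if info["message"] != "Integration successful.":
                reached = float(info["tcur"][-1]) if len(info["tcur"]) else t0
                raise SimulationError(
                    f"integration failed in [{t0}, {t1}] s (reached t={reached}): "
                    f"{info['message']}",
                    time_reached=reached,
                )
            seg_t, seg_y = t_grid[1:], out[1:]
        else:
            sol = solve_ivp(
                rhs, (t0, t1), y, args=(model,), method=method,
                rtol=rtol, atol=atol, t_eval=grid, dense_output=False,
            )
            if not sol.success:
                reached = float(sol.t[-1]) if sol.t.size else t0
                raise SimulationError(
                    f"integration failed in [{t0}, {t1}] s (reached t={reached}): {sol.message}",
                    time_reached=reached,
                )
            seg_t, seg_y = sol.t, sol.y.T
        times.append(seg_t)
        states.append(seg_y.copy())
        y = seg_y[-1].copy()

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    # drop the pre-event duplicate of each event time (keep the later, post-event row)
    keep = np.ones(len(t_all), dtype=bool)
    for i in range(len(t_all) - 1):
        if t_all[i + 1] == t_all[i]:
            keep[i] = False
    t_all, y_all = t_all[keep], y_all[keep]

    # recompute fluxes and forces on the grid; both depend only on the state
    # (the live coefficient values travel inside the state vector)
    forces = _forces_on_grid(y_all, model)
    fluxes = _fluxes_on_grid(y_all, forces, model)

    return Trajectory(
        params=params, times=t_all, states=y_all, fluxes=fluxes, forces=forces,
        events=schedule.events, glucose_time=glucose_time,
    )


def _forces_on_grid(states: np.ndarray, model: Model) -> np.ndarray:
    """Vectorized force evaluation: rows of (X_H, X_K, X_Na, X_Cl, X_Ar)."""
    geom = model.geometry
    z = np.array([ion.z for ion in IONS], dtype=float)
    X = np.empty((len(states), 5))
    c = states[:, :8]
    X[:, :4] = geom.R * np.log(c[:, 1::2] / c[:, 0::2]) + z * geom.F * states[:, [8]] / geom.temperature
    atp = model.atp
    X[:, 4] = (geom.R / atp.c_atp_eq) * (states[:, 9] - atp.c_atp_eq) * (1.0 + atp.k_eq)
    return X


def _fluxes_on_grid(states: np.ndarray, forces: np.ndarray, model: Model) -> np.ndarray:
    """Vectorized J = L X with the live dynamic coefficients of each row."""
    from .model_core import _compiled  # local import to keep the helper private

    comp = _compiled(model)
    J = forces @ comp.L0.T
    dyn = states[:, 10:]
    for k, (i, j) in enumerate(comp.dyn_ij):
        J[:, i] += dyn[:, k] * forces[:, j]
        if i != j:
            J[:, j] += dyn[:, k] * forces[:, i]
    return J


def build_reference_scenarios(
    dose: float, output_step: float = 1.0, second_dose: float = 10.0
) -> dict[str, ScenarioSchedule]:
    """The four canonical stimulus schedules for one KCl dose (mM).

    * ``fit``: KCl at 300 s, glucose at 600 s (the fitting protocol);
    * ``standard``: KCl at 300 s, glucose at 660 s (the headline simulation);
    * ``validation``: KCl at 180 s, glucose at 300 s (chloride validation);
    * ``second_stimulus``: standard timing plus a second KCl addition at 1000 s.
    """
    if dose <= 0:
        raise ValueError("KCl dose must be positive")
    kcl = lambda t, a: StimulusEvent(t, "kcl_addition", a)
    glc = lambda t: StimulusEvent(t, "glucose")
    return {
        "fit": ScenarioSchedule((kcl(300.0, dose), glc(600.0)), span=1200.0, output_step=output_step),
        "standard": ScenarioSchedule((kcl(300.0, dose), glc(660.0)), span=1200.0, output_step=output_step),
        "validation": ScenarioSchedule((kcl(180.0, dose), glc(300.0)), span=900.0, output_step=output_step),
        "second_stimulus": ScenarioSchedule(
            (kcl(300.0, dose), glc(660.0), kcl(1000.0, second_dose)),
            span=1400.0, output_step=output_step,
        ),
    }
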