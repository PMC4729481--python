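"""Post-hoc analyses of simulated trajectories.

What drives the potassium flux?  With couplings restricted to H+ and K+ (the
no-K+-ATPase model class), the net K+ flux splits exactly in two alternative
ways:

* by ion:        J_K(H) = L_KH X_H,                J_K(K) = L_KK X_K;
* by potential:  J_K(CP) = R (L_KH ln rH + L_KK ln rK),
                 J_K(EP) = (L_KH + L_KK) F dphi / T,

with r_i = c_i_in / c_i_out and J_K = sum of the two components in either
split.  The module also extracts the predicted chloride and sodium fluxes,
simulates the second-KCl-stimulus protocol, and provides local
finite-difference parameter sensitivities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import ModelError
from .parameters import ParameterSet
from .scenarios import KCL_DOSES_MM, Trajectory, build_reference_scenarios, simulate

__all__ = [
    "DecompositionSeries",
    "SecondStimulusSummary",
    "decompose_JK_by_ion",
    "decompose_JK_by_potential",
    "potential_ratio_after_glucose",
    "predict_anion_and_sodium",
    "second_stimulus_response",
    "local_sensitivity",
]


@dataclass(frozen=True)
class DecompositionSeries:
    """Two flux components, their sum, and an optional (masked) ratio series."""

    times: np.ndarray
    components: Mapping[str, np.ndarray]
    total: np.ndarray
    ratio: "np.ma.MaskedArray | None" = None
    ratio_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times, **dict(self.components), "J_K": self.total}
        if self.ratio is not None:
            cols[self.ratio_name] = self.ratio.filled(np.nan)
        return pd.DataFrame(cols)


def _check_k_couplings(params: ParameterSet) -> None:
    """The two-way splits assume K+ couples only to H+ (and itself)."""
    for other in ("Na", "Cl", "Ar"):
        entry = params.matrix.get("K", other)
        value = getattr(entry, "target_aG", entry)
        init = getattr(entry, "init_value", entry)
        if value != 0.0 or init != 0.0:
            raise ModelError(
                f"decomposition requires L_K{other} = 0, but parameter set "
                f"{params.name!r} has a nonzero L_K{other}"
            )


def decompose_JK_by_ion(traj: Trajectory, params: "ParameterSet | None" = None) -> DecompositionSeries:
    """Split J_K into its H+-driven and K+-driven parts, J_K(H) + J_K(K) = J_K."""
    params = params or traj.params
    _check_k_couplings(params)
    L_KH = traj.coefficient_series("H", "K")
    L_KK = traj.coefficient_series("K", "K")
    X_H = traj.forces[:, 0]
    X_K = traj.forces[:, 1]
    jk_h = L_KH * X_H
    jk_k = L_KK * X_K
    return DecompositionSeries(
        times=traj.times,
        components={"J_K(H)": jk_h, "J_K(K)": jk_k},
        total=jk_h + jk_k,
    )


def decompose_JK_by_potential(
    traj: Trajectory, params: "ParameterSet | None" = None, ratio_floor: float = 0.0
) -> DecompositionSeries:
    """Split J_K into chemical-potential and electrical-potential parts.

    The ratio J_K(EP)/J_K(CP) is masked (not an error) wherever
    |J_K(CP)| <= ratio_floor.
    """
    params = params or traj.params
    _check_k_couplings(params)
    geom = params.geometry
    L_KH = traj.coefficient_series("H", "K")
    L_KK = traj.coefficient_series("K", "K")
    ln_rh = np.log(traj.concentration("H", "in") / traj.concentration("H", "out"))
    ln_rk = np.log(traj.concentration("K", "in") / traj.concentration("K", "out"))
    jk_cp = geom.R * (L_KH * ln_rh + L_KK * ln_rk)
    jk_ep = (L_KH + L_KK) * geom.F * traj.delta_phi / geom.temperature
    ratio = np.ma.masked_where(np.abs(jk_cp) <= ratio_floor, jk_ep / np.where(jk_cp == 0, np.nan, jk_cp))
    return DecompositionSeries(
        times=traj.times,
        components={"J_K(CP)": jk_cp, "J_K(EP)": jk_ep},
        total=jk_cp + jk_ep,
        ratio=ratio,
        ratio_name="J_K(EP)/J_K(CP)",
    )


def potential_ratio_after_glucose(traj: Trajectory, delay: float = 5.0) -> float:
    """|J_K(EP)/J_K(CP)| at the first output grid point >= ``delay`` seconds
    after the glucose event — the operational reading of "directly after
    glucose addition"."""
    if traj.glucose_time is None:
        raise ModelError("trajectory has no glucose event")
    dec = decompose_JK_by_potential(traj)
    idx = np.searchsorted(traj.times, traj.glucose_time + delay)
    if idx >= len(traj.times):
        raise ModelError("trajectory ends before the readout time")
    value = dec.ratio[idx]
    if np.ma.is_masked(value):
        raise ModelError("J_K(CP) vanishes at the readout time")
    return abs(float(value))


@dataclass(frozen=True)
class AnionSodiumPrediction:
    """Predicted Cl- and Na+ flux series with negligibility/ordering flags."""

    times: np.ndarray
    j_cl: np.ndarray
    j_na: np.ndarray
    peak_cl_influx: float  # max inward Cl- flux magnitude, mol m^-2 s^-1
    peak_na_magnitude: float
    na_negligible: bool
    na_threshold: float


def predict_anion_and_sodium(
    traj: Trajectory, na_fraction: float = 0.01, window: "tuple[float, float] | None" = None
) -> AnionSodiumPrediction:
    """Extract the predicted Cl- and Na+ fluxes and flag Na+ negligibility.

    Na+ is negligible when max|J_Na| stays below ``na_fraction`` of max|J_K|
    over the (optional) time window.
    """
    mask = np.ones_like(traj.times, dtype=bool)
    if window is not None:
        mask = (traj.times >= window[0]) & (traj.times <= window[1])
    j_cl = traj.flux("Cl")
    j_na = traj.flux("Na")
    j_k = traj.flux("K")
    peak_cl_influx = float(np.clip(-j_cl[mask], 0.0, None).max())
    peak_na = float(np.abs(j_na[mask]).max())
    threshold = na_fraction * float(np.abs(j_k[mask]).max())
    return AnionSodiumPrediction(
        times=traj.times,
        j_cl=j_cl,
        j_na=j_na,
        peak_cl_influx=peak_cl_influx,
        peak_na_magnitude=peak_na,
        na_negligible=peak_na <= threshold,
        na_threshold=threshold,
    )


def chloride_peak_by_dose(
    params: ParameterSet,
    doses: Sequence[float] = KCL_DOSES_MM,
    scenario: str = "standard",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[float, float]:
    """Peak Cl- influx magnitude (mol m^-2 s^-1) per KCl dose, post-stimulus."""
    peaks = {}
    for dose in doses:
        schedule = build_reference_scenarios(dose)[scenario]
        traj = simulate(schedule, params, rtol=rtol, atol=atol)
        t_kcl = schedule.events[0].time
        pred = predict_anion_and_sodium(traj, window=(t_kcl, schedule.span))
        peaks[dose] = pred.peak_cl_influx
    return peaks


@dataclass(frozen=True)
class SecondStimulusSummary:
    """Peak responses around the glucose and second-KCl events for one run."""

    first_dose: float
    second_dose: float
    trajectory: Trajectory
    post_glucose_peak: Mapping[str, float]  # max |J_ion| between glucose and 2nd KCl
    post_second_peak: Mapping[str, float]  # max |J_ion| after the 2nd KCl
    h_influx_transient: bool  # J_H sign change to influx shortly after 2nd KCl
    h_min_after_second: float


def second_stimulus_response(
    params: ParameterSet,
    first_dose: float,
    second_dose: float = 10.0,
    detection_window: float = 60.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SecondStimulusSummary:
    """Simulate the double-stimulus protocol (KCl, glucose, second KCl).

    The transient H+ influx after the second stimulus is detected as a sign
    change of J_H: efflux (positive) immediately before the second addition
    turning into influx (negative) within ``detection_window`` seconds after.
    """
    if first_dose <= 0 or second_dose <= 0:
        raise ValueError("doses must be positive")
    schedule = build_reference_scenarios(first_dose, second_dose=second_dose)["second_stimulus"]
    traj = simulate(schedule, params, rtol=rtol, atol=atol)
    t_glc = schedule.events[1].time
    t_second = schedule.events[2].time
    mid = (traj.times >= t_glc) & (traj.times < t_second)
    post = traj.times >= t_second
    win = (traj.times >= t_second) & (traj.times <= t_second + detection_window)
    before = (traj.times >= t_second - 10.0) & (traj.times < t_second)
    j_h = traj.flux("H")
    post_glucose = {ion: float(np.abs(traj.flux(ion)[mid]).max()) for ion in ("H", "K", "Cl")}
    post_second = {ion: float(np.abs(traj.flux(ion)[post]).max()) for ion in ("H", "K", "Cl")}
    transient = bool(j_h[before].mean() > 0 and j_h[win].min() < 0)
    return SecondStimulusSummary(
        first_dose=first_dose,
        second_dose=second_dose,
        trajectory=traj,
        post_glucose_peak=post_glucose,
        post_second_peak=post_second,
        h_influx_transient=transient,
        h_min_after_second=float(j_h[win].min()),
    )


@dataclass(frozen=True)
class SensitivityEntry:
    parameter: str
    sensitivity: float  # d ln|observable| / d ln p (relative central difference)
    ok: bool
    note: str = ""


def local_sensitivity(
    params: ParameterSet,
    observable: Callable[[ParameterSet], float],
    parameter_names: Sequence[str],
    rel_step: float = 0.05,
) -> list[SensitivityEntry]:
    """Central finite-difference relative sensitivities of a scalar observable.

    For positive parameters the perturbation is symmetric in log space
    (p -> p * exp(+-h)); parameters that are zero or negative are perturbed
    additively-relative (p -> p (1 +- h)).  A non-finite observable at a
    perturbed point flags the entry instead of raising.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    base_value = observable(params)
    entries = []
    for name in parameter_names:
        current = _lookup(params, name)
        try:
            if current > 0:
                up = observable(params.with_updates({name: current * math.exp(rel_step)}))
                dn = observable(params.with_updates({name: current * math.exp(-rel_step)}))
            else:
                up = observable(params.with_updates({name: current * (1 + rel_step)}))
                dn = observable(params.with_updates({name: current * (1 - rel_step)}))
        except Exception as err:  # noqa: BLE001 - flagged, not raised
            entries.append(SensitivityEntry(name, math.nan, False, f"evaluation failed: {err}"))
            continue
        if not (math.isfinite(up) and math.isfinite(dn)):
            entries.append(SensitivityEntry(name, math.nan, False, "non-finite observable"))
            continue
        if base_value == 0:
            entries.append(SensitivityEntry(name, math.nan, False, "observable is zero at base point"))
            continue
        sens = (up - dn) / (2 * rel_step * base_value)
        entries.append(SensitivityEntry(name, float(sens), True))
    return entries


def _lookup(params: ParameterSet, name: str) -> float:
    for section in ("coefficients", "global", "initial"):
        block = params.raw.get(section, {})
        if name in block:
            return float(block[name])
    raise KeyError(f"unknown parameter {name!r}")
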