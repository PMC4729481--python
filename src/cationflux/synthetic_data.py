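"""MIFE-like synthetic flux datasets with known ground truth.

The microelectrode ion flux (MIFE) experiments deliver per-condition net-flux
traces for K+ and H+ (nmol m^-2 s^-1) sampled every few seconds over ~20 min,
with a KCl addition and a glucose addition during the recording.  This module
generates datasets of exactly that shape from the model, so the estimation and
analysis layers are testable without the original measurements.  Measurement
scatter is emulated as independent Gaussian noise with a relative and an
absolute (floor) component; it does not model electrode physics.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet, load_parameter_set
from .scenarios import KCL_DOSES_MM, ScenarioSchedule, build_reference_scenarios, simulate

__all__ = [
    "NoiseModel",
    "FluxDataset",
    "FluxParseError",
    "generate",
    "read_flux_csv",
    "write_flux_csv",
    "read_flux_xlsx",
    "make_fixture_suite",
]

#: model fluxes are mol m^-2 s^-1; MIFE traces are reported in nmol m^-2 s^-1
MOL_TO_NMOL = 1e9
_COLUMNS = ["condition", "ion", "time_s", "flux_nmol_m2_s"]
_KNOWN_IONS = {"H", "K", "Na", "Cl"}


class FluxParseError(ValueError):
    """Malformed flux file; the message names the offending row."""


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: sd = relative_sd * |flux| + floor_sd."""

    relative_sd: float = 0.05
    floor_sd: float = 2.0  # nmol m^-2 s^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.floor_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class FluxDataset:
    """Net-flux records per condition and ion, with sign-convention metadata.

    ``data`` columns: condition (label), ion (H/K/Na/Cl), time_s,
    flux_nmol_m2_s.  ``sign_convention`` is ``"outward_positive"`` (the model
    convention) or ``"influx_positive"``; readers convert on load.
    """

    data: pd.DataFrame
    sign_convention: str = "outward_positive"
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sign_convention not in ("outward_positive", "influx_positive"):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        df = self.data.reset_index(drop=True)[_COLUMNS].copy()
        bad = set(df["ion"]) - _KNOWN_IONS
        if bad:
            raise FluxParseError(f"unknown ion labels: {sorted(bad)}")
        for (cond, ion), grp in df.groupby(["condition", "ion"], sort=False):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise FluxParseError(f"times not strictly increasing in trace ({cond}, {ion})")
        object.__setattr__(self, "data", df)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["condition"]))

    @property
    def n_traces(self) -> int:
        return self.data.groupby(["condition", "ion"]).ngroups

    def trace(self, condition: str, ion: str) -> pd.DataFrame:
        mask = (self.data["condition"] == condition) & (self.data["ion"] == ion)
        return self.data[mask].reset_index(drop=True)

    def to_outward_positive(self) -> "FluxDataset":
        if self.sign_convention == "outward_positive":
            return self
        df = self.data.copy()
        df["flux_nmol_m2_s"] = -df["flux_nmol_m2_s"]
        return replace(self, data=df, sign_convention="outward_positive")


def _sample_times(schedule: ScenarioSchedule, sample_step: float) -> np.ndarray:
    return np.arange(0.0, schedule.span + 1e-9, sample_step)


def generate(
    params: ParameterSet,
    schedule: ScenarioSchedule,
    sample_step: float = 5.0,
    noise: "NoiseModel | None" = None,
    ions: Sequence[str] = ("K", "H"),
    condition: str = "",
    trajectory: "Trajectory | None" = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FluxDataset:
    """Simulate the scenario and sample noisy net fluxes on a regular grid.

    Deterministic for a fixed noise seed.  ``trajectory`` may pass in a
    pre-computed simulation (its output grid must contain the sample times).
    """
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    noise = noise or NoiseModel(relative_sd=0.0, floor_sd=0.0)
    if trajectory is None:
        grid_schedule = replace_output_step(schedule, sample_step)
        trajectory = simulate(grid_schedule, params, rtol=rtol, atol=atol)
    t_samp = _sample_times(schedule, sample_step)
    rng = np.random.default_rng(noise.seed)
    label = condition or f"KCl_{_dose_of(schedule)}mM"
    frames = []
    for ion in ions:
        series = np.interp(t_samp, trajectory.times, trajectory.flux(ion)) * MOL_TO_NMOL
        sd = noise.relative_sd * np.abs(series) + noise.floor_sd
        noisy = series + rng.normal(0.0, 1.0, size=series.shape) * sd
        frames.append(pd.DataFrame({
            "condition": label, "ion": ion, "time_s": t_samp, "flux_nmol_m2_s": noisy,
        }))
    prov = {
        "kind": "synthetic",
        "parameter_set": params.name,
        "seed": noise.seed,
        "relative_sd": noise.relative_sd,
        "floor_sd": noise.floor_sd,
        "sample_step_s": sample_step,
        "events": [(e.time, e.kind, e.amount) for e in schedule.events],
    }
    return FluxDataset(pd.concat(frames, ignore_index=True), "outward_positive", prov)


def replace_output_step(schedule: ScenarioSchedule, step: float) -> ScenarioSchedule:
    return ScenarioSchedule(schedule.events, schedule.span, output_step=step)


def _dose_of(schedule: ScenarioSchedule) -> float:
    for e in schedule.events:
        if e.kind == "kcl_addition":
            return e.amount
    return 0.0


def make_fixture_suite(
    seed: int = 0,
    params: "ParameterSet | None" = None,
    scenario: str = "fit",
    sample_step: float = 5.0,
    noise: "NoiseModel | None" = None,
) -> FluxDataset:
    """The four-dose K+/H+ bundle mirroring the experimental design (8 traces).

    Generated from P2a with the fit-scenario timing and default noise; each
    condition label records its KCl dose.  Per-condition noise seeds are
    derived deterministically from ``seed``.
    """
    params = params or load_parameter_set("P2a")
    base = noise or NoiseModel(seed=seed)
    parts, prov_events = [], {}
    for k, dose in enumerate(KCL_DOSES_MM):
        schedule = build_reference_scenarios(dose, output_step=sample_step)[scenario]
        nm = replace(base, seed=seed * 1000 + k)
        ds = generate(params, schedule, sample_step=sample_step, noise=nm,
                      condition=f"KCl_{dose}mM")
        parts.append(ds.data)
        prov_events[f"KCl_{dose}mM"] = ds.provenance["events"]
    prov = {
        "kind": "synthetic", "parameter_set": params.name, "seed": seed,
        "scenario": scenario, "relative_sd": base.relative_sd,
        "floor_sd": base.floor_sd, "sample_step_s": sample_step,
        "events": prov_events,
    }
    return FluxDataset(pd.concat(parts, ignore_index=True), "outward_positive", prov)


# ---------------------------------------------------------------------------
# file I/O: a plain-CSV dialect with a '# key: value' metadata header
# ---------------------------------------------------------------------------

def write_flux_csv(dataset: FluxDataset, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sign_convention: {dataset.sign_convention}\n")
        for key, value in dataset.provenance.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        dataset.data.to_csv(fh, index=False)


def read_flux_csv(path: "str | Path") -> FluxDataset:
    """Read a flux CSV; influx-positive files are converted to outward-positive."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if ":" not in line:
                    raise FluxParseError(f"{path}:{lineno}: malformed metadata line")
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append((lineno, line))
    if not body_lines:
        raise FluxParseError(f"{path}: no table found")
    header_lineno, header = body_lines[0]
    cols = [c.strip() for c in header.strip().split(",")]
    missing = set(_COLUMNS) - set(cols)
    if missing:
        raise FluxParseError(f"{path}:{header_lineno}: missing columns {sorted(missing)}")
    df = pd.read_csv(io.StringIO("".join(line for _, line in body_lines)), dtype={"condition": str})
    for offset, row in enumerate(df.itertuples(index=False)):
        lineno = body_lines[1 + offset][0]
        try:
            float(getattr(row, "time_s"))
            float(getattr(row, "flux_nmol_m2_s"))
        except (TypeError, ValueError):
            raise FluxParseError(f"{path}:{lineno}: non-numeric time or flux") from None
        if getattr(row, "ion") not in _KNOWN_IONS:
            raise FluxParseError(f"{path}:{lineno}: unknown ion label {getattr(row, 'ion')!r}")
    convention = meta.pop("sign_convention", "outward_positive")
    parsed_meta = {}
    for key, value in meta.items():
        try:
            parsed_meta[key] = json.loads(value)
        except (json.JSONDecodeError, ValueError):
            parsed_meta[key] = value
    try:
        ds = FluxDataset(df, convention, dict(parsed_meta, source=str(path)))
    except FluxParseError as err:
        raise FluxParseError(f"{path}: {err}") from None
    return ds.to_outward_positive()


def read_flux_xlsx(
    path: "str | Path",
    sign_convention: str = "outward_positive",
    sheet_name: "int | str" = 0,
) -> FluxDataset:
    """Convenience importer for spreadsheet flux tables (columns as in the CSV
    dialect).  Optional: the test suite never requires spreadsheet input."""
    df = pd.read_excel(path, sheet_name=sheet_name)
    ds = FluxDataset(df, sign_convention, {"source": str(path)})
    return ds.to_outward_positive()
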