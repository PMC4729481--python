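"""Loading and validation of parameter sets (P1, P2a, P2b or user files).

A parameter set bundles the geometry, the phenomenological coefficient matrix
(static entries plus glucose-activated dynamic ones), the ATP balance
parameters and the initial state.  The three fitted sets from the study ship
with the package as YAML files whose keys mirror the printed tables
(L_HHinit, L_HHaG, k_incrHH, ..., K, C_ATP, delta_phi, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .model_core import (
    ATPParams,
    CoefficientMatrix,
    ConfigurationError,
    DynamicCoefficient,
    Geometry,
    Model,
    StateLayout,
    SystemState,
    buffering_factor,
    ph_to_concentration_mM,
)

__all__ = ["ParameterSet", "load_parameter_set", "BUILTIN_SETS"]

BUILTIN_SETS = ("P1", "P2a", "P2b")

_GLOBAL_KEYS = {"V_in", "V_out", "T", "Surf", "pbc", "cf", "K", "C_ATP", "delta_phi"}
_GLOBAL_OPTIONAL = {"Cm"}
_INITIAL_KEYS = {
    "H_out", "K_out", "Cl_out", "Na_out", "pH_in", "K_in", "Cl_in", "Na_in",
    "ATP", "ATP_stimulus",
}
#: coefficient pairs that may appear, mapped from table key fragments
_STATIC_L = {
    "L_HK": ("H", "K"), "L_HNa": ("H", "Na"), "L_HCl": ("H", "Cl"),
    "L_KNa": ("K", "Na"), "L_KCl": ("K", "Cl"), "L_NaCl": ("Na", "Cl"),
    "L_KK": ("K", "K"), "L_NaNa": ("Na", "Na"), "L_ClCl": ("Cl", "Cl"),
    "L_HH": ("H", "H"),
}
#: dynamic coefficient triples: (init key or None, target key, rate key)
_DYNAMIC_L = {
    ("H", "H"): ("L_HHinit", "L_HHaG", "k_incrHH"),
    ("K", "K"): ("L_KKinit", "L_KKaG", "k_incrKK"),
    ("H", "Ar"): (None, "L_HAraG", "k_incrHAr"),
    ("K", "Ar"): (None, "L_KAraG", "k_incrKAr"),
}


@dataclass(frozen=True)
class ParameterSet:
    """A fully resolved model configuration plus its initial state."""

    name: str
    variant: str  # "M1" (L_KAr free) or "M2" (L_KAr = 0)
    geometry: Geometry
    matrix: CoefficientMatrix
    atp: ATPParams
    initial: Mapping[str, float]  # raw initial-condition block (mM / V / pH)
    raw: Mapping[str, Any]  # the parsed config, for round-tripping updates

    @property
    def layout(self) -> StateLayout:
        return StateLayout(tuple(k for k, _ in self.matrix.dynamic_items))

    @property
    def bf(self) -> float:
        """Constant buffering factor, from pbc and the initial internal H+."""
        return buffering_factor(self.geometry.pbc, self.c_h_in_initial)

    @property
    def c_h_in_initial(self) -> float:
        return ph_to_concentration_mM(float(self.initial["pH_in"]), self.geometry.cf)

    def model(self, glucose_active: bool = False, buffering: str = "constant") -> Model:
        return Model(
            geometry=self.geometry,
            matrix=self.matrix,
            atp=self.atp,
            bf=self.bf,
            glucose_active=glucose_active,
            buffering=buffering,
        )

    def initial_state(self) -> SystemState:
        """State vector at t = 0 (pre-glucose: dynamic L at their init values)."""
        layout = self.layout
        y = np.empty(layout.size)
        ini = self.initial
        y[layout.c_out("H")] = float(ini["H_out"])
        y[layout.c_in("H")] = self.c_h_in_initial
        for ion in ("K", "Na", "Cl"):
            y[layout.c_out(ion)] = float(ini[f"{ion}_out"])
            y[layout.c_in(ion)] = float(ini[f"{ion}_in"])
        y[layout.I_DPHI] = float(self.raw["global"]["delta_phi"])
        y[layout.I_ATP] = float(ini["ATP"])
        for k, (_, coef) in enumerate(self.matrix.dynamic_items):
            y[layout.N_FIXED + k] = coef.init_value
        state = SystemState(layout, y, t=0.0)
        state.validate()
        return state

    def derived_quantities(self) -> dict[str, float]:
        """Quantities computed from the printed values (reported at load time)."""
        out = {"Bf": self.bf, "k_ATPdecr": self.atp.k_atp_decr, "H_in_mM": self.c_h_in_initial}
        for (a, b), coef in self.matrix.dynamic_items:
            out[f"k_decr{a}{b}"] = coef.k_decr
        return out

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterSet":
        """A new set with table-keyed values replaced (used by the estimator).

        Keys are the table names (``L_KK``, ``L_HHinit``, ``k_incrHAr``,
        ``K_in``, ``delta_phi``, ``K``, ``C_ATP``, ...).
        """
        raw = {k: dict(v) if isinstance(v, dict) else v for k, v in self.raw.items()}
        for key, value in updates.items():
            placed = False
            for section in ("coefficients", "global", "initial"):
                if key in raw.get(section, {}):
                    raw[section][key] = float(value)
                    placed = True
                    break
            if not placed:
                if key.startswith(("L_", "k_")):
                    raw.setdefault("coefficients", {})[key] = float(value)
                else:
                    raise ConfigurationError(f"unknown parameter key {key!r}")
        return _build(raw, self.name)


def _require(section: Mapping[str, Any], keys: set[str], where: str) -> None:
    missing = sorted(keys - set(section))
    if missing:
        raise ConfigurationError(f"missing keys in {where}: {missing}")


def _build_matrix(coef: Mapping[str, float]) -> CoefficientMatrix:
    entries: dict[tuple[str, str], float | DynamicCoefficient] = {}
    used: set[str] = set()
    for pair, (init_key, target_key, rate_key) in _DYNAMIC_L.items():
        if target_key in coef:
            if rate_key not in coef:
                raise ConfigurationError(f"{target_key} given without its rate {rate_key}")
            init = float(coef[init_key]) if init_key and init_key in coef else 0.0
            entries[pair] = DynamicCoefficient(
                init_value=init, target_aG=float(coef[target_key]), k_incr=float(coef[rate_key])
            )
            used |= {k for k in (init_key, target_key, rate_key) if k}
    for key, pair in _STATIC_L.items():
        if key in coef and key not in used:
            if pair in entries:
                raise ConfigurationError(f"coefficient {key} conflicts with dynamic entry {pair}")
            entries[pair] = float(coef[key])
            used.add(key)
    unknown = set(coef) - used - {"k_ATPincr"}
    if unknown:
        raise ConfigurationError(f"unknown coefficient keys: {sorted(unknown)}")
    for (a, b), v in entries.items():
        if a == b and isinstance(v, float) and v < 0:
            raise ConfigurationError(f"straight coefficient L_{a}{a} must be >= 0, got {v}")
    return CoefficientMatrix(entries)


def _build(raw: Mapping[str, Any], default_name: str) -> ParameterSet:
    for section in ("global", "initial", "coefficients"):
        if section not in raw:
            raise ConfigurationError(f"parameter file lacks section {section!r}")
    g, ini, coef = raw["global"], raw["initial"], raw["coefficients"]
    _require(g, _GLOBAL_KEYS, "global")
    _require(ini, _INITIAL_KEYS, "initial")
    extra = set(g) - _GLOBAL_KEYS - _GLOBAL_OPTIONAL
    if extra:
        raise ConfigurationError(f"unknown global keys: {sorted(extra)}")
    geometry = Geometry(
        surf=float(g["Surf"]),
        v_in=float(g["V_in"]),
        v_out=float(g["V_out"]),
        temperature=float(g["T"]),
        cm=float(g.get("Cm", 0.01)),
        pbc=float(g["pbc"]),
        cf=float(g["cf"]),
    )
    matrix = _build_matrix(coef)
    atp = ATPParams(
        c_atp_eq=float(g["C_ATP"]),
        k_eq=float(g["K"]),
        atp_stimulus=float(ini["ATP_stimulus"]),
        k_atp_incr=float(coef.get("k_ATPincr", 0.0)),
    )
    variant = str(raw.get("variant") or ("M1" if matrix.get("K", "Ar") != 0.0 else "M2"))
    if variant == "M2" and matrix.get("K", "Ar") != 0.0:
        raise ConfigurationError("variant M2 requires L_KAr = 0")
    name = str(raw.get("name", default_name))
    ps = ParameterSet(
        name=name, variant=variant, geometry=geometry, matrix=matrix, atp=atp,
        initial={k: float(v) for k, v in ini.items()}, raw=raw,
    )
    ps.initial_state()  # validates positivity of the initial concentrations
    return ps


def load_parameter_set(name_or_path: "str | Path") -> ParameterSet:
    """Load a built-in parameter set (``"P1"``, ``"P2a"``, ``"P2b"``) or a YAML file."""
    name = str(name_or_path)
    if name in BUILTIN_SETS:
        text = resources.files("cationflux.paramsets").joinpath(f"{name}.yaml").read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ConfigurationError(
                f"unknown parameter set {name!r}: not one of {BUILTIN_SETS} and no such file"
            )
        text = path.read_text()
        name = path.stem
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file {name!r} did not parse to a mapping")
    return _build(raw, name)
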