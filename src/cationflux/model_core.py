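"""Force, flux and balance equations of the linear non-equilibrium-thermodynamic
membrane-transport model.

The model describes net fluxes of H+, K+, Na+ and Cl- across the yeast plasma
membrane together with the ATP->ADP hydrolysis rate as linear combinations of
their conjugate thermodynamic forces,

    J_i = sum_j L_ij * X_j,

where the forces are differences of electrochemical potential over temperature,
X_i = R ln(c_in/c_out) + z_i F dphi / T for the ions and X_Ar = A_Ar / T for the
reaction, and L is the symmetric matrix of phenomenological (Onsager)
coefficients.  Fluxes are outward-directed positive; the membrane potential is
dphi = phi_in - phi_out.

All functions here are pure: they map a state vector and a frozen model
configuration to derivatives, so they can be handed directly to a stiff ODE
integrator.  Units are SI (mol, m, s, V, J) with concentrations carried in mM,
exploiting the identity 1 mM = 1 mol m^-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "FARADAY",
    "IonSpecies",
    "IONS",
    "ION_INDEX",
    "SPECIES5",
    "Geometry",
    "DynamicCoefficient",
    "CoefficientMatrix",
    "ATPParams",
    "StateLayout",
    "SystemState",
    "Model",
    "ModelError",
    "ConcentrationError",
    "ConfigurationError",
    "ph_to_concentration_mM",
    "concentration_mM_to_ph",
    "buffering_factor",
    "electrochemical_force",
    "atp_affinity",
    "force_vector",
    "ion_fluxes",
    "concentration_derivatives",
    "atp_derivative",
    "coefficient_derivative",
    "membrane_potential_derivative",
    "entropy_production",
    "rhs",
]

#: gas constant, J mol^-1 K^-1
R_GAS = 8.31446261815324
#: Faraday constant, C mol^-1 (as used throughout the parameter tables)
FARADAY = 96485.0


class ModelError(Exception):
    """Base class for model contract violations."""


class ConcentrationError(ModelError, ValueError):
    """A concentration left the positive domain of the model."""


class ConfigurationError(ModelError, ValueError):
    """Inconsistent or invalid model configuration."""


@dataclass(frozen=True)
class IonSpecies:
    """A transported ion: name and (signed) charge number."""

    name: str
    z: int

    def __post_init__(self) -> None:
        if self.z not in (-1, 1):
            raise ConfigurationError(f"charge number of {self.name} must be +-1, got {self.z}")


#: the four transported species, in fixed model order
IONS: tuple[IonSpecies, ...] = (
    IonSpecies("H", +1),
    IonSpecies("K", +1),
    IonSpecies("Na", +1),
    IonSpecies("Cl", -1),
)
ION_INDEX: dict[str, int] = {ion.name: i for i, ion in enumerate(IONS)}
#: row/column order of the phenomenological matrix (ions + ATP reaction)
SPECIES5: tuple[str, ...] = ("H", "K", "Na", "Cl", "Ar")
_S5_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECIES5)}


def ph_to_concentration_mM(ph: float, cf: float = 1000.0) -> float:
    """Free proton concentration in mM for a given pH (cf converts M -> mM)."""
    return cf * 10.0 ** (-ph)


def concentration_mM_to_ph(c_mM: float, cf: float = 1000.0) -> float:
    if c_mM <= 0:
        raise ConcentrationError(f"proton concentration must be positive, got {c_mM} mM")
    return -math.log10(c_mM / cf)


def buffering_factor(pbc_mM_per_pH: float, c_h_in_mM: float) -> float:
    """Dimensionless buffering factor Bf relating proton flux to free-proton change.

    A buffer capacity of ``pbc`` mM per pH unit means d(bound H)/d(pH) = -pbc,
    while the free pool satisfies d(free H)/d(pH) = -ln(10) * c_H.  The fraction
    of added protons that stays free is therefore 1/Bf with
    Bf = pbc / (ln 10 * c_H).
    """
    if c_h_in_mM <= 0:
        raise ConcentrationError("internal proton concentration must be positive")
    return pbc_mM_per_pH / (math.log(10.0) * c_h_in_mM)


@dataclass(frozen=True)
class Geometry:
    """Cell-suspension geometry, electrical and thermal constants.

    The default construction mirrors the experimental monolayer: a population
    of round cells (diameter 4.5 um, volume 50 fL = 5e-17 m^3) in a 3 ml bath, giving a
    total surface of 2.29e-5 m^2 and internal volume of 1.8e-11 m^3.
    """

    surf: float  # m^2, total cell surface
    v_in: float  # m^3, total internal volume
    v_out: float  # m^3, bath volume
    temperature: float = 296.0  # K
    cm: float = 0.01  # F m^-2, specific membrane capacitance
    pbc: float = 200.0  # mM per pH unit
    cf: float = 1000.0  # mM per M
    R: float = R_GAS
    F: float = FARADAY

    def __post_init__(self) -> None:
        for name in ("surf", "v_in", "v_out", "temperature", "cm", "pbc", "cf", "R", "F"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"Geometry.{name} must be strictly positive")

    @classmethod
    def from_cell_monolayer(
        cls,
        n_cells: float = 3.6e5,
        cell_diameter: float = 4.5e-6,
        cell_volume: float = 5e-17,
        v_out: float = 2.85e-6,
        **kwargs: float,
    ) -> "Geometry":
        """Total surface/volume from per-cell geometry of a round yeast cell."""
        surf = n_cells * math.pi * cell_diameter**2
        v_in = n_cells * cell_volume
        return cls(surf=surf, v_in=v_in, v_out=v_out, **kwargs)


@dataclass(frozen=True)
class DynamicCoefficient:
    """A phenomenological coefficient that relaxes to a new value after glucose.

    While inactive (pre-glucose) the coefficient is pinned at ``init_value``.
    Once activated it follows dL/dt = k_incr - k_decr * L with
    k_decr = k_incr / target_aG, i.e. an exponential relaxation toward the
    post-glucose asymptote ``target_aG``.
    """

    init_value: float  # mol^2 J^-1 m^-2 s^-1
    target_aG: float  # mol^2 J^-1 m^-2 s^-1
    k_incr: float  # mol^2 J^-1 m^-2 s^-2

    def __post_init__(self) -> None:
        if self.target_aG == 0 and self.k_incr != 0:
            raise ConfigurationError("dynamic coefficient with zero target but nonzero k_incr")

    @property
    def k_decr(self) -> float:
        """Relaxation rate, s^-1; defined so that k_decr * target_aG = k_incr."""
        if self.k_incr == 0:
            return 0.0
        return self.k_incr / self.target_aG


@dataclass(frozen=True)
class CoefficientMatrix:
    """Symmetric 5x5 matrix of phenomenological coefficients over (H, K, Na, Cl, Ar).

    Only one triangle is stored (keys are order-normalized pairs), so Onsager
    reciprocity L_ij = L_ji holds by construction.  Entries are either plain
    floats or :class:`DynamicCoefficient` instances.
    """

    entries: Mapping[tuple[str, str], "float | DynamicCoefficient"]

    def __post_init__(self) -> None:
        normalized: dict[tuple[str, str], float | DynamicCoefficient] = {}
        for (a, b), value in self.entries.items():
            if a not in _S5_INDEX or b not in _S5_INDEX:
                raise ConfigurationError(f"unknown species in coefficient ({a},{b})")
            key = (a, b) if _S5_INDEX[a] <= _S5_INDEX[b] else (b, a)
            if key in normalized and normalized[key] != value:
                raise ConfigurationError(f"conflicting entries for coefficient {key}")
            normalized[key] = value
        object.__setattr__(self, "entries", normalized)
        for (a, b), value in normalized.items():
            if a == b:
                lo = value if isinstance(value, float) else min(value.init_value, value.target_aG)
                if lo < 0:
                    raise ConfigurationError(f"straight coefficient L_{a}{b} must be >= 0, got {value}")

    def get(self, a: str, b: str) -> "float | DynamicCoefficient":
        key = (a, b) if _S5_INDEX[a] <= _S5_INDEX[b] else (b, a)
        return self.entries.get(key, 0.0)

    @property
    def dynamic_items(self) -> tuple[tuple[tuple[str, str], DynamicCoefficient], ...]:
        """Dynamic entries in deterministic (row-major) order."""
        return tuple(
            (key, v) for key, v in sorted(self.entries.items(), key=lambda kv: (_S5_INDEX[kv[0][0]], _S5_INDEX[kv[0][1]]))
            if isinstance(v, DynamicCoefficient)
        )

    def dense(self, dynamic_values: Sequence[float] | None = None) -> np.ndarray:
        """Dense symmetric 5x5 array; dynamic entries taken from ``dynamic_values``
        (in ``dynamic_items`` order) or from their ``init_value`` when omitted."""
        L = np.zeros((5, 5))
        dyn = {k: v for k, v in self.dynamic_items}
        if dynamic_values is None:
            live = {k: v.init_value for k, v in dyn.items()}
        else:
            keys = list(dyn)
            if len(dynamic_values) != len(keys):
                raise ConfigurationError(
                    f"expected {len(keys)} dynamic values, got {len(dynamic_values)}"
                )
            live = dict(zip(keys, dynamic_values))
        for (a, b), value in self.entries.items():
            x = live[(a, b)] if isinstance(value, DynamicCoefficient) else float(value)
            i, j = _S5_INDEX[a], _S5_INDEX[b]
            L[i, j] = x
            L[j, i] = x
        return L

    def is_psd(self, dynamic_values: Sequence[float] | None = None, tol: float = 0.0) -> bool:
        eig = np.linalg.eigvalsh(self.dense(dynamic_values))
        return bool(eig.min() >= -abs(tol))


@dataclass(frozen=True)
class ATPParams:
    """ATP balance parameters: dATP/dt = k_atp_incr - k_atp_decr * ATP.

    The decay constant is tied to the post-glucose asymptote via
    k_atp_decr = k_atp_incr / atp_stimulus.  Before the glucose event the cells
    are starved: production is off and the ATP pool is frozen at its initial
    value (both rate constants zero).
    """

    c_atp_eq: float  # mM, equilibrium ATP concentration (printed C_ATP)
    k_eq: float  # dimensionless reaction equilibrium constant (printed K)
    atp_stimulus: float  # mM, post-glucose asymptote
    k_atp_incr: float  # mol m^-3 s^-1 == mM s^-1

    def __post_init__(self) -> None:
        if self.c_atp_eq <= 0:
            raise ConfigurationError("equilibrium ATP concentration must be positive")
        for name in ("k_eq", "atp_stimulus", "k_atp_incr"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"ATPParams.{name} must be non-negative")

    @property
    def k_atp_decr(self) -> float:
        """s^-1; zero when production is zero (pre-glucose freeze)."""
        if self.k_atp_incr == 0:
            return 0.0
        return self.k_atp_incr / self.atp_stimulus


@dataclass(frozen=True)
class StateLayout:
    """Index map of the flat ODE state vector.

    Order: 8 concentrations (out/in per ion, model ion order), membrane
    potential, ATP, then the live values of the dynamic coefficients in
    :attr:`CoefficientMatrix.dynamic_items` order.
    """

    dynamic_keys: tuple[tuple[str, str], ...]

    I_DPHI = 8
    I_ATP = 9
    N_FIXED = 10

    @property
    def size(self) -> int:
        return self.N_FIXED + len(self.dynamic_keys)

    def c_out(self, ion: str) -> int:
        return 2 * ION_INDEX[ion]

    def c_in(self, ion: str) -> int:
        return 2 * ION_INDEX[ion] + 1

    def dynamic(self, a: str, b: str) -> int:
        key = (a, b) if _S5_INDEX[a] <= _S5_INDEX[b] else (b, a)
        return self.N_FIXED + self.dynamic_keys.index(key)

    def names(self) -> list[str]:
        out = []
        for ion in IONS:
            out += [f"c_{ion.name}_out", f"c_{ion.name}_in"]
        out += ["delta_phi", "c_ATP"]
        out += [f"L_{a}{b}" for a, b in self.dynamic_keys]
        return out


@dataclass(frozen=True)
class SystemState:
    """A named view of one point of the flat state vector."""

    layout: StateLayout
    vector: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (self.layout.size,):
            raise ConfigurationError(f"state vector must have shape ({self.layout.size},)")
        object.__setattr__(self, "vector", v)

    def c_out(self, ion: str) -> float:
        return float(self.vector[self.layout.c_out(ion)])

    def c_in(self, ion: str) -> float:
        return float(self.vector[self.layout.c_in(ion)])

    @property
    def delta_phi(self) -> float:
        return float(self.vector[self.layout.I_DPHI])

    @property
    def c_atp(self) -> float:
        return float(self.vector[self.layout.I_ATP])

    @property
    def dynamic_values(self) -> np.ndarray:
        return self.vector[self.layout.N_FIXED :]

    def validate(self) -> None:
        for ion in IONS:
            for side, c in (("out", self.c_out(ion.name)), ("in", self.c_in(ion.name))):
                if not c > 0:
                    raise ConcentrationError(
                        f"non-positive {ion.name} concentration ({side}): {c} mM at t={self.t}"
                    )
        if not math.isfinite(self.delta_phi):
            raise ModelError(f"membrane potential not finite at t={self.t}")


@dataclass(frozen=True)
class Model:
    """Frozen model configuration for one integration phase.

    ``glucose_active`` switches ATP production and the relaxation of dynamic
    coefficients on; it is toggled by the glucose stimulus event.  ``bf`` is
    the constant buffering factor; with ``buffering='dynamic'`` it is
    recomputed from the instantaneous internal proton concentration instead.
    """

    geometry: Geometry
    matrix: CoefficientMatrix
    atp: ATPParams
    bf: float
    glucose_active: bool = False
    buffering: str = "constant"  # or "dynamic"

    def __post_init__(self) -> None:
        if self.buffering not in ("constant", "dynamic"):
            raise ConfigurationError(f"unknown buffering mode {self.buffering!r}")
        if self.bf <= 0:
            raise ConfigurationError("buffering factor must be positive")

    @property
    def layout(self) -> StateLayout:
        return StateLayout(tuple(k for k, _ in self.matrix.dynamic_items))

    def with_glucose(self) -> "Model":
        return replace(self, glucose_active=True)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def electrochemical_force(
    ion: IonSpecies, c_in: float, c_out: float, delta_phi: float, geom: Geometry
) -> float:
    """Thermodynamic force conjugate to the outward flux of ``ion``.

    X_i = R ln(c_in/c_out) + z_i F dphi / T  (J mol^-1 K^-1).  The standard
    chemical potential cancels between the two compartments and never appears.
    """
    if c_in <= 0 or c_out <= 0:
        raise ConcentrationError(
            f"non-positive {ion.name} concentration: c_in={c_in}, c_out={c_out} mM"
        )
    return geom.R * math.log(c_in / c_out) + ion.z * geom.F * delta_phi / geom.temperature


def atp_affinity(atp: ATPParams, c_atp: float, geom: Geometry) -> float:
    """Affinity A_Ar (J mol^-1) of ATP hydrolysis at ATP concentration ``c_atp``:
    A = (R T / c_eq) (c - c_eq) (1 + K_eq).  Positive when ATP exceeds its
    equilibrium concentration, i.e. when hydrolysis can drive transport."""
    return (
        geom.R
        * geom.temperature
        / atp.c_atp_eq
        * (c_atp - atp.c_atp_eq)
        * (1.0 + atp.k_eq)
    )


def force_vector(state: SystemState, model: Model) -> np.ndarray:
    """All five forces (X_H, X_K, X_Na, X_Cl, X_Ar) at ``state``; X_Ar = A_Ar/T."""
    geom = model.geometry
    X = np.empty(5)
    for i, ion in enumerate(IONS):
        X[i] = electrochemical_force(ion, state.c_in(ion.name), state.c_out(ion.name), state.delta_phi, geom)
    X[4] = atp_affinity(model.atp, state.c_atp, geom) / geom.temperature
    return X


def ion_fluxes(state: SystemState, matrix: CoefficientMatrix, model: Model) -> np.ndarray:
    """Net outward fluxes (J_H, J_K, J_Na, J_Cl, J_Ar) in mol m^-2 s^-1.

    J = L X with L the live symmetric coefficient matrix at ``state``; the last
    component is the phenomenological ATP-reaction rate, kept as a diagnostic
    (the ATP pool itself evolves by its own balance equation).
    """
    L = matrix.dense(state.dynamic_values)
    if not np.allclose(L, L.T):
        raise ModelError("coefficient matrix is not symmetric")
    if np.any(np.diag(L) < 0):
        raise ModelError("negative straight coefficient in live matrix")
    return L @ force_vector(state, model)


def concentration_derivatives(fluxes: np.ndarray, geom: Geometry, bf: float) -> np.ndarray:
    """Time derivatives of the 8 concentrations (mM/s), in state-vector order.

    dc_out/dt = J S/V_out and dc_in/dt = -J S/V_in for each ion; the internal
    proton pool is additionally divided by the buffering factor ``bf``.
    """
    d = np.empty(8)
    for i, ion in enumerate(IONS):
        j = fluxes[i]
        d[2 * i] = j * geom.surf / geom.v_out
        d[2 * i + 1] = -j * geom.surf / geom.v_in
    d[1] /= bf  # internal H+ is buffered
    return d


def atp_derivative(atp: ATPParams, c_atp: float, glucose_active: bool = True) -> float:
    """dATP/dt (mM/s); zero before glucose (starved cells, pool frozen)."""
    if not glucose_active:
        return 0.0
    return atp.k_atp_incr - atp.k_atp_decr * c_atp


def coefficient_derivative(coef: DynamicCoefficient, value: float, active: bool = True) -> float:
    """dL/dt (mol^2 J^-1 m^-2 s^-2) of one dynamic coefficient."""
    if not active:
        return 0.0
    return coef.k_incr - coef.k_decr * value


def membrane_potential_derivative(fluxes: np.ndarray, geom: Geometry) -> float:
    """d(dphi)/dt = -(2 F / C_m)(J_H + J_K + J_Na - J_Cl), V/s.

    The factor 2 is part of the model definition and kept literally.
    """
    charge_flux = fluxes[0] + fluxes[1] + fluxes[2] - fluxes[3]
    return -(2.0 * geom.F / geom.cm) * charge_flux


def entropy_production(state: SystemState, model: Model) -> float:
    """Isothermal entropy production density sigma = sum_i J_i X_i.

    Non-negative whenever the live coefficient matrix is positive
    semidefinite (sigma = X^T L X)."""
    X = force_vector(state, model)
    J = ion_fluxes(state, model.matrix, model)
    return float(J @ X)


try:  # numba accelerates the inner ODE kernel; the numpy fallback is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=False)
def _rhs_kernel(y, L0, dyn_i, dyn_j, k_incr, k_decr, z, cst, glucose):
    """Derivative kernel; cst = (R, F, T, c_atp_eq, 1+K_eq, Surf/V_out,
    Surf/V_in, Bf, 2F/Cm, k_ATPincr, k_ATPdecr)."""
    n_dyn = dyn_i.size
    L = L0.copy()
    for k in range(n_dyn):
        L[dyn_i[k], dyn_j[k]] = y[10 + k]
        L[dyn_j[k], dyn_i[k]] = y[10 + k]
    X = np.empty(5)
    phit = cst[1] * y[8] / cst[2]
    for i in range(4):
        X[i] = cst[0] * np.log(y[2 * i + 1] / y[2 * i]) + z[i] * phit
    X[4] = (cst[0] / cst[3]) * (y[9] - cst[3]) * cst[4]
    J = L @ X
    d = np.empty(y.size)
    for i in range(4):
        d[2 * i] = J[i] * cst[5]
        d[2 * i + 1] = -J[i] * cst[6]
    d[1] /= cst[7]
    d[8] = -cst[8] * (J[0] + J[1] + J[2] - J[3])
    if glucose:
        d[9] = cst[9] - cst[10] * y[9]
        for k in range(n_dyn):
            d[10 + k] = k_incr[k] - k_decr[k] * y[10 + k]
    else:
        d[9] = 0.0
        for k in range(n_dyn):
            d[10 + k] = 0.0
    return d


class _Compiled:
    """Precomputed arrays for fast right-hand-side evaluation of one model."""

    __slots__ = ("L0", "dyn_ij", "dyn_i", "dyn_j", "k_incr", "k_decr", "z", "cst")

    def __init__(self, model: Model) -> None:
        matrix = model.matrix
        dyn = matrix.dynamic_items
        self.L0 = matrix.dense([0.0] * len(dyn))
        self.dyn_ij = [( _S5_INDEX[a], _S5_INDEX[b]) for (a, b), _ in dyn]
        self.dyn_i = np.array([i for i, _ in self.dyn_ij], dtype=np.int64)
        self.dyn_j = np.array([j for _, j in self.dyn_ij], dtype=np.int64)
        self.k_incr = np.array([c.k_incr for _, c in dyn])
        self.k_decr = np.array([c.k_decr for _, c in dyn])
        self.z = np.array([ion.z for ion in IONS], dtype=float)
        g, atp = model.geometry, model.atp
        self.cst = np.array([
            g.R, g.F, g.temperature, atp.c_atp_eq, 1.0 + atp.k_eq,
            g.surf / g.v_out, g.surf / g.v_in, model.bf, 2.0 * g.F / g.cm,
            atp.k_atp_incr, atp.k_atp_decr,
        ])


def _compiled(model: Model) -> _Compiled:
    comp = getattr(model, "_comp_cache", None)
    if comp is None:
        comp = _Compiled(model)
        object.__setattr__(model, "_comp_cache", comp)
    return comp


def live_matrix(model: Model, dynamic_values: np.ndarray) -> np.ndarray:
    """Dense symmetric coefficient matrix with the given live dynamic values."""
    comp = _compiled(model)
    L = comp.L0.copy()
    for k, (i, j) in enumerate(comp.dyn_ij):
        L[i, j] = dynamic_values[k]
        L[j, i] = dynamic_values[k]
    return L


def rhs(t: float, y: np.ndarray, model: Model) -> np.ndarray:
    """Full derivative vector of the model at time ``t``; pure in (t, y).

    Layout: 8 concentration derivatives, d(dphi)/dt, dATP/dt, then the dynamic
    coefficient derivatives in matrix order.
    """
    y = np.asarray(y, dtype=float)
    comp = _compiled(model)
    if np.any(y[:8] <= 0.0) or not np.isfinite(y[8]):
        # rebuild through the checked path for an informative error
        state = SystemState(model.layout, y, t=t)
        state.validate()
    cst = comp.cst
    if model.buffering == "dynamic":
        cst = cst.copy()
        cst[7] = buffering_factor(model.geometry.pbc, y[1])
    return _rhs_kernel(
        y, comp.L0, comp.dyn_i, comp.dyn_j, comp.k_incr, comp.k_decr,
        comp.z, cst, model.glucose_active,
    )
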