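"""Fitting phenomenological coefficients and initial conditions to flux data.

The estimation follows the study protocol: a particle-swarm optimizer (swarm
40, iteration limit 400, stall criterion on the swarm's objective standard
deviation) restarted many times with randomized start points and randomized
parameter bounds drawn inside the declared envelope; straight coefficients
L_ii are constrained non-negative, cross coefficients may take either sign.
If the best parameter ends up on a boundary, that boundary is extended by a
factor of 100 and one follow-up estimation is run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .model_core import CoefficientMatrix, ConfigurationError
from .parameters import ParameterSet
from .scenarios import ScenarioSchedule, SimulationError, simulate
from .synthetic_data import MOL_TO_NMOL, FluxDataset

__all__ = [
    "INITIAL_CONDITION_RANGES",
    "ParameterSpec",
    "FitProblem",
    "PSOResult",
    "FitResult",
    "OnsagerReport",
    "objective",
    "particle_swarm",
    "multistart",
    "validate_onsager",
]

_ROLES = ("straight_L", "cross_L", "dynamic_rate", "initial_condition", "global")

#: experimentally verified estimation ranges for the initial conditions
#: ("estimated between ..."), usable directly as ParameterSpec bounds
INITIAL_CONDITION_RANGES: dict[str, tuple[float, float]] = {
    "ATP": (0.0, 2.5),        # mM
    "pH_in": (5.0, 7.0),
    "K_in": (60.0, 100.0),    # mM
    "Cl_in": (0.1, 10.0),     # mM
    "Na_in": (5.0, 30.0),     # mM
    "Na_out": (0.01, 0.1),    # mM
}


@dataclass(frozen=True)
class ParameterSpec:
    """One free parameter: its table key, role, and estimation envelope."""

    name: str
    role: str
    lower: float
    upper: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigurationError(f"unknown parameter role {self.role!r}")
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ConfigurationError(f"bounds of {self.name} must be finite")
        if self.lower >= self.upper:
            raise ConfigurationError(f"empty bound interval for {self.name}")
        if self.role == "straight_L" and self.lower < 0:
            raise ConfigurationError(
                f"straight coefficient {self.name} must have lower bound >= 0"
            )

    @property
    def positive(self) -> bool:
        return self.lower >= 0


@dataclass(frozen=True)
class FitProblem:
    """Datasets, free-parameter specs and shared scenario schedules for a fit.

    All conditions are simulated with the same parameters; only the KCl dose
    (encoded in the per-condition schedule) differs.  ``weighting`` is
    ``"per_trace"`` (each trace weighted by the inverse of its mean squared
    flux, so K+ and H+ traces of different magnitude contribute comparably) or
    ``"unweighted"``.
    """

    base_params: ParameterSet
    specs: tuple[ParameterSpec, ...]
    dataset: FluxDataset
    schedules: Mapping[str, ScenarioSchedule]
    variant: str = "M2"
    weighting: str = "per_trace"
    rtol: float = 1e-6
    atol: float = 1e-9
    penalty: float = 1e6

    def __post_init__(self) -> None:
        if not self.specs:
            raise ConfigurationError("no free parameters specified")
        if self.weighting not in ("per_trace", "unweighted"):
            raise ConfigurationError(f"unknown weighting {self.weighting!r}")
        if self.variant not in ("M1", "M2"):
            raise ConfigurationError(f"unknown model variant {self.variant!r}")
        if self.variant == "M2" and self.base_params.matrix.get("K", "Ar") != 0.0:
            raise ConfigurationError("variant M2 requires L_KAr = 0 in the base parameter set")
        ds = self.dataset.to_outward_positive()
        object.__setattr__(self, "dataset", ds)
        missing = set(ds.conditions) - set(self.schedules)
        if missing:
            raise ConfigurationError(f"no schedule for conditions {sorted(missing)}")
        object.__setattr__(self, "specs", tuple(self.specs))

    @classmethod
    def from_dataset(
        cls,
        base_params: ParameterSet,
        dataset: FluxDataset,
        specs: Sequence[ParameterSpec],
        **kwargs,
    ) -> "FitProblem":
        """Build per-condition schedules from the dataset's provenance events."""
        from .scenarios import StimulusEvent

        events_meta = dataset.provenance.get("events")
        if events_meta is None:
            raise ConfigurationError("dataset provenance lacks stimulus events")
        step = float(dataset.provenance.get("sample_step_s", 5.0))
        schedules = {}
        for cond in dataset.conditions:
            # either one shared event list or a per-condition mapping
            events = events_meta.get(cond) if isinstance(events_meta, Mapping) else events_meta
            if events is None:
                raise ConfigurationError(f"no stimulus events recorded for condition {cond!r}")
            evts = tuple(StimulusEvent(t, kind, a) for t, kind, a in events)
            span = float(dataset.trace(cond, dataset.data["ion"].iloc[0])["time_s"].max())
            schedules[cond] = ScenarioSchedule(evts, span=max(span, evts[-1].time + step), output_step=step)
        return cls(base_params, tuple(specs), dataset, schedules, **kwargs)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([(s.lower, s.upper) for s in self.specs])

    def parameters_from_vector(self, theta: Sequence[float]) -> ParameterSet:
        updates = {s.name: float(v) for s, v in zip(self.specs, theta)}
        return self.base_params.with_updates(updates)

    def trace_weights(self) -> dict[tuple[str, str], float]:
        weights: dict[tuple[str, str], float] = {}
        for (cond, ion), grp in self.dataset.data.groupby(["condition", "ion"], sort=False):
            if self.weighting == "unweighted":
                weights[(cond, ion)] = 1.0
            else:
                msq = float(np.mean(grp["flux_nmol_m2_s"].to_numpy() ** 2))
                weights[(cond, ion)] = 1.0 / msq if msq > 0 else 1.0
        return weights


def objective(theta: Sequence[float], problem: FitProblem) -> float:
    """Weighted sum of squared residuals between simulated and measured fluxes.

    Simulation failures return a large finite penalty (scaled by how much of
    the horizon was missed) so the swarm can continue past stiff corners.
    """
    try:
        params = problem.parameters_from_vector(theta)
    except (ConfigurationError, ValueError):
        return problem.penalty * 2.0
    weights = problem.trace_weights()
    total = 0.0
    for cond in problem.dataset.conditions:
        schedule = problem.schedules[cond]
        try:
            traj = simulate(schedule, params, rtol=problem.rtol, atol=problem.atol)
        except SimulationError as err:
            reached = getattr(err, "time_reached", 0.0)
            shortfall = max(0.0, 1.0 - reached / schedule.span)
            return problem.penalty * (1.0 + shortfall)
        except (ValueError, FloatingPointError):
            return problem.penalty * 2.0
        ions = dict.fromkeys(problem.dataset.data["ion"])
        for ion in ions:
            trace = problem.dataset.trace(cond, ion)
            if trace.empty:
                continue
            sim = np.interp(trace["time_s"].to_numpy(), traj.times, traj.flux(ion)) * MOL_TO_NMOL
            res = sim - trace["flux_nmol_m2_s"].to_numpy()
            total += weights[(cond, ion)] * float(res @ res)
    return total


@dataclass(frozen=True)
class PSOResult:
    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # best objective after each iteration
    n_iterations: int
    seed: int
    stalled: bool


def particle_swarm(
    fun: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    swarm_size: int = 40,
    n_iterations: int = 400,
    seed: int = 0,
    stall_sd: float = 1e-6,
    inertia: float = 0.729,
    cognitive: float = 1.49445,
    social: float = 1.49445,
) -> PSOResult:
    """Global-best particle swarm minimization inside a box.

    Standard constriction-type update: each particle keeps a personal best,
    the swarm a global best; velocities are clamped to half the bound width
    and positions clipped to the box.  Terminates at the iteration limit or
    when the standard deviation of the swarm's objective values drops below
    ``stall_sd``.  Deterministic for a fixed seed (Mersenne-Twister stream).
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ConfigurationError("bounds must have shape (n_params, 2)")
    if swarm_size < 2:
        raise ConfigurationError("swarm_size must be >= 2")
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    vmax = 0.5 * width
    rng = np.random.Generator(np.random.MT19937(seed))

    x = lo + rng.random((swarm_size, len(lo))) * width
    v = (rng.random((swarm_size, len(lo))) - 0.5) * width
    f = np.array([fun(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])

    history = []
    stalled = False
    it = 0
    for it in range(1, n_iterations + 1):
        r1 = rng.random((swarm_size, len(lo)))
        r2 = rng.random((swarm_size, len(lo)))
        v = inertia * v + cognitive * r1 * (pbest_x - x) + social * r2 * (gbest_x - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        f = np.array([fun(xi) for xi in x])
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_f)
        if float(np.std(f)) < stall_sd:
            stalled = True
            break
    return PSOResult(gbest_x, gbest_f, np.array(history), it, seed, stalled)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a (multistart) estimation."""

    parameters: dict[str, float]
    x: np.ndarray
    objective: float
    run_history: tuple[tuple[int, float], ...]  # (run seed, best objective)
    seed: int
    extension_log: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "objective": self.objective,
            "seed": self.seed,
            "runs": [{"seed": s, "objective": f} for s, f in self.run_history],
            "extensions": list(self.extension_log),
        }


def _random_bounds(spec: ParameterSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Random sub-interval of the declared envelope: log-uniform endpoints for
    positive parameters, uniform otherwise."""
    if spec.positive:
        floor = spec.lower if spec.lower > 0 else spec.upper * 1e-6
        a, b = np.exp(rng.uniform(np.log(floor), np.log(spec.upper), size=2))
    else:
        a, b = rng.uniform(spec.lower, spec.upper, size=2)
    lo, hi = (a, b) if a < b else (b, a)
    if not hi > lo:
        lo, hi = spec.lower, spec.upper
    return float(lo), float(hi)


def multistart(
    problem: FitProblem,
    n_runs: int = 50,
    seed: int = 0,
    swarm_size: int = 40,
    n_iterations: int = 400,
    stall_sd: float = 1e-6,
    randomize_bounds: bool = True,
    boundary_rtol: float = 1e-3,
    max_extension_rounds: int = 2,
    extension_factor: float = 100.0,
) -> FitResult:
    """Multistart PSO over the problem's parameter envelope.

    Each run draws its own bounds inside the envelope (free parameters with
    ``fixed=True`` keep their lower bound as a constant).  The best run wins;
    if any winning parameter sits on its envelope boundary, that boundary is
    extended by ``extension_factor`` and one follow-up estimation is run, for
    at most ``max_extension_rounds`` rounds.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    free = [s for s in problem.specs if not s.fixed]
    fixed = {s.name: s.lower for s in problem.specs if s.fixed}
    if not free:
        raise ConfigurationError("all parameters are fixed")

    def fun_for(specs_order: Sequence[ParameterSpec]) -> Callable[[np.ndarray], float]:
        names = [s.name for s in specs_order]

        def fun(x: np.ndarray) -> float:
            theta = dict(zip(names, x), **fixed)
            return objective([theta[s.name] for s in problem.specs], problem)

        return fun

    envelope = {s.name: (s.lower, s.upper) for s in free}
    extension_log: list[str] = []

    def run_round(round_seed: int):
        ss = np.random.SeedSequence([seed, round_seed])
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
        fun = fun_for(free)
        best: "PSOResult | None" = None
        best_bounds: "np.ndarray | None" = None
        hist = []
        for rs in run_seeds:
            if randomize_bounds:
                brng = np.random.Generator(np.random.MT19937(rs))
                bnds = np.array([
                    _random_bounds(ParameterSpec(s.name, s.role, *envelope[s.name]), brng)
                    for s in free
                ])
            else:
                bnds = np.array([envelope[s.name] for s in free])
            res = particle_swarm(fun, bnds, swarm_size, n_iterations, rs, stall_sd)
            hist.append((rs, res.best_f))
            if best is None or res.best_f < best.best_f:
                best, best_bounds = res, bnds
        return best, best_bounds, tuple(hist)

    best, best_bounds, hist = run_round(0)
    for round_idx in range(1, max_extension_rounds + 1):
        # a winning parameter sitting on the bounds it was optimized under
        # signals that the admissible range was too narrow
        extended = False
        for k, s in enumerate(free):
            lo, hi = best_bounds[k]
            env_lo, env_hi = envelope[s.name]
            width = hi - lo
            xk = best.best_x[k]
            if abs(xk - hi) <= boundary_rtol * width:
                new_hi = hi * extension_factor if hi > 0 else hi / extension_factor
                if new_hi > env_hi:
                    envelope[s.name] = (env_lo, new_hi)
                    extension_log.append(
                        f"round {round_idx}: upper bound of {s.name} extended x{extension_factor:g}"
                    )
                    extended = True
            elif abs(xk - lo) <= boundary_rtol * width and lo != 0.0:
                new_lo = lo * extension_factor if lo < 0 else lo / extension_factor
                if new_lo < env_lo:
                    envelope[s.name] = (new_lo, env_hi)
                    extension_log.append(
                        f"round {round_idx}: lower bound of {s.name} extended x{extension_factor:g}"
                    )
                    extended = True
        if not extended:
            break
        follow, follow_bounds, follow_hist = run_round(round_idx)
        hist = hist + follow_hist
        if follow.best_f < best.best_f:
            best, best_bounds = follow, follow_bounds

    parameters = dict(zip((s.name for s in free), (float(v) for v in best.best_x)), **fixed)
    x_full = np.array([parameters[s.name] for s in problem.specs])
    return FitResult(parameters, x_full, best.best_f, hist, seed, tuple(extension_log))


@dataclass(frozen=True)
class OnsagerReport:
    """Thermodynamic admissibility report for a coefficient matrix."""

    diagonal_ok: bool  # hard: all L_ii >= 0
    symmetric: bool  # structural: always true for CoefficientMatrix
    psd_ok: bool  # warning-level: eigenvalues/determinant non-negative
    determinant: float
    eigenvalues: tuple[float, ...]
    messages: tuple[str, ...]

    @property
    def passed(self) -> bool:
        """Hard checks only; a PSD warning does not fail the report."""
        return self.diagonal_ok and self.symmetric


def validate_onsager(
    matrix: CoefficientMatrix,
    dynamic_values: "Sequence[float] | None" = None,
    psd_tol: float = 1e-12,
) -> OnsagerReport:
    """Check L_ii >= 0 (hard), symmetry (structural) and positive
    semidefiniteness / det >= 0 (warning-level)."""
    L = matrix.dense(dynamic_values)
    messages = []
    diag = np.diag(L)
    diagonal_ok = bool(np.all(diag >= 0))
    if not diagonal_ok:
        for name, v in zip(("H", "K", "Na", "Cl", "Ar"), diag):
            if v < 0:
                messages.append(f"hard violation: L_{name}{name} = {v:g} < 0")
    symmetric = bool(np.allclose(L, L.T, rtol=0, atol=0))
    eig = np.linalg.eigvalsh(L)
    scale = max(1.0, float(np.abs(L).max()))
    psd_ok = bool(eig.min() >= -psd_tol * scale)
    if not psd_ok:
        messages.append(
            f"warning: matrix not positive semidefinite (min eigenvalue {eig.min():g})"
        )
    det = float(np.linalg.det(L))
    return OnsagerReport(
        diagonal_ok=diagonal_ok,
        symmetric=symmetric,
        psd_ok=psd_ok,
        determinant=det,
        eigenvalues=tuple(float(e) for e in eig),
        messages=tuple(messages),
    )
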