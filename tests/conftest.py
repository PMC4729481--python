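"""Shared fixtures: parameter sets, canonical trajectories, and the (expensive)
parameter-recovery experiments, computed once per session."""

import pytest

import cationflux as cf
from cationflux.estimation import FitProblem, ParameterSpec, multistart
from cationflux.scenarios import ScenarioSchedule, StimulusEvent
from cationflux.synthetic_data import NoiseModel, generate


@pytest.fixture(scope="session")
def p2a() -> cf.ParameterSet:
    return cf.load_parameter_set("P2a")


@pytest.fixture(scope="session")
def p2b() -> cf.ParameterSet:
    return cf.load_parameter_set("P2b")


@pytest.fixture(scope="session")
def p1() -> cf.ParameterSet:
    return cf.load_parameter_set("P1")


@pytest.fixture(scope="session")
def standard_traj(p2a) -> cf.Trajectory:
    """P2a, 10 mM KCl at 300 s, glucose at 660 s, 1 s output grid."""
    schedule = cf.build_reference_scenarios(10.0)["standard"]
    return cf.simulate(schedule, p2a)


@pytest.fixture(scope="session")
def dose_trajs(p2a) -> dict[float, cf.Trajectory]:
    """The four KCl doses of the experimental design, standard timing."""
    out = {}
    for dose in cf.KCL_DOSES_MM:
        schedule = cf.build_reference_scenarios(dose)["standard"]
        out[dose] = cf.simulate(schedule, p2a)
    return out


@pytest.fixture(scope="session")
def short_schedule() -> ScenarioSchedule:
    """A compressed stimulus protocol used for estimation tests: same event
    structure as the experiments, shorter horizon for speed."""
    return ScenarioSchedule(
        (StimulusEvent(60.0, "kcl_addition", 10.0), StimulusEvent(180.0, "glucose")),
        span=360.0,
        output_step=10.0,
    )


_RECOVERY_TRUTH = {"L_KK": 1.88e-8, "L_ClCl": 3.08e-7, "L_HCl": 3.84e-7}


def _recovery_specs(envelope: float = 30.0) -> tuple[ParameterSpec, ...]:
    t = _RECOVERY_TRUTH
    return (
        ParameterSpec("L_KK", "straight_L", t["L_KK"] / envelope, t["L_KK"] * envelope),
        ParameterSpec("L_ClCl", "straight_L", t["L_ClCl"] / envelope, t["L_ClCl"] * envelope),
        ParameterSpec("L_HCl", "cross_L", -t["L_HCl"] * envelope, t["L_HCl"] * envelope),
    )


def _run_recovery(p2a, short_schedule, noise: NoiseModel):
    dataset = generate(p2a, short_schedule, sample_step=10.0, noise=noise,
                       condition="KCl_10mM")
    problem = FitProblem(
        p2a, _recovery_specs(), dataset, {"KCl_10mM": short_schedule},
        rtol=1e-6, atol=1e-9,
    )
    # the envelope contains the generating values by construction, so the
    # boundary-extension rounds of the full protocol are not exercised here
    result = multistart(problem, n_runs=20, seed=7, swarm_size=10,
                        n_iterations=80, stall_sd=1e-9,
                        max_extension_rounds=0)
    rel_err = {
        name: abs(result.parameters[name] - true) / abs(true)
        for name, true in _RECOVERY_TRUTH.items()
    }
    return result, rel_err


@pytest.fixture(scope="session")
def recovery_noiseless(p2a, short_schedule):
    """Ground-truth recovery from noise-free synthetic fluxes."""
    return _run_recovery(p2a, short_schedule, NoiseModel(0.0, 0.0, seed=0))


@pytest.fixture(scope="session")
def recovery_noisy(p2a, short_schedule):
    """Recovery with 5% relative measurement noise."""
    return _run_recovery(p2a, short_schedule, NoiseModel(0.05, 0.0, seed=11))
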