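import pytest

from funcan import extract_features, integrate, make_scenario

SCENARIOS = ("baseline", "exposure", "reappraisal", "cbt")


@pytest.fixture(scope="session")
def scenario_runs():
    """Resolved (spec, plan, trajectory) for every bundled scenario (RK solver)."""
    runs = {}
    for name in SCENARIOS:
        spec, plan = make_scenario(name)
        traj = integrate(spec, plan)
        runs[name] = (spec, plan, traj)
    return runs


@pytest.fixture(scope="session")
def baseline_run(scenario_runs):
    return scenario_runs["baseline"]


@pytest.fixture(scope="session")
def scenario_reports(scenario_runs):
    return {
        name: extract_features(traj, plan)
        for name, (spec, plan, traj) in scenario_runs.items()
    }
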