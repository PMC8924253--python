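import pytest

from scave import assignment, simulate
from scave.types import WheelConfig

#: gap-based strictness: an exerciser that enters or leaves the wheel
#: mid-minute is still detected for part of that minute, so recovery
#: checks use the most permissive detected-fraction threshold
GAP_CONFIG = WheelConfig(strictness=1.0)


@pytest.fixture(scope="session")
def scenarios():
    return {name: simulate.make_scenario(name) for name in "ABC"}


@pytest.fixture(scope="session")
def week_sim():
    """4 mice, 7 days, no confounds: the clean ground-truth recovery cage."""
    cfg = simulate.SimConfig(seed=101, duration_days=7.0, p_bystander=0.0)
    return simulate.simulate_cage(cfg)


@pytest.fixture(scope="session")
def week_sim_assigned(week_sim):
    return assignment.assign_ve(week_sim.events, week_sim.ve, GAP_CONFIG)


@pytest.fixture(scope="session")
def confounded_sim():
    """Same cage with bystanders slipping under the wheel and artifact
    rotation minutes injected."""
    cfg = simulate.SimConfig(
        seed=202, duration_days=7.0, p_bystander=0.15, p_artifact_minute=0.001
    )
    return simulate.simulate_cage(cfg)


@pytest.fixture(scope="session")
def confounded_sim_assigned(confounded_sim):
    return assignment.assign_ve(confounded_sim.events, confounded_sim.ve, GAP_CONFIG)


def minute_index(result_minute, cfg) -> int:
    return int(round((result_minute - cfg.start).total_seconds())) // 60


def matches_truth(result, truth) -> bool:
    """Credited set and status agree with the ground-truth prediction.

    The discard reason code is a reporting detail (it depends on whether a
    detected animal happened to sit on a wheel antenna), not something the
    ground truth constrains."""
    k = minute_index(result.minute_start, truth.config)
    expected = truth.expected_assignment(k, result.rot_total)
    return (
        result.minute_start == expected.minute_start
        and result.rot_total == expected.rot_total
        and result.credited == expected.credited
        and result.status == expected.status
    )
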