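import numpy as np
import pytest

from pfbt import (
    ModelParams,
    ProbeTrial,
    SamplingTrial,
    TaskConfig,
    TaskSequence,
    generate_task_sequence,
    simulate_responses,
    simulate_trajectory,
)


def make_sequence(
    trial_types,
    outcomes,
    probe_after=(),
    probe_agents=(),
    p_self=0.5,
    p_other=0.5,
) -> TaskSequence:
    """Hand-build a small task sequence for oracle tests."""
    sampling = tuple(
        SamplingTrial(
            index=i + 1,
            trial_type=tt,
            outcome=int(o),
            p_self=p_self,
            p_other=p_other,
            walk_used="self" if tt != "decoy" else "other",
        )
        for i, (tt, o) in enumerate(zip(trial_types, outcomes))
    )
    probes = tuple(
        ProbeTrial(index=after + k + 1, after_sampling_index=after, probe_agent=agent)
        for k, (after, agent) in enumerate(zip(probe_after, probe_agents))
    )
    return TaskSequence(sampling, probes)


@pytest.fixture(scope="session")
def default_sequence() -> TaskSequence:
    return generate_task_sequence(TaskConfig(seed=123))


@pytest.fixture(scope="session")
def short_sequence() -> TaskSequence:
    return generate_task_sequence(TaskConfig(n_sampling_trials=120, seed=5))


@pytest.fixture(scope="session")
def low_noise_participant(default_sequence):
    """A simulated participant with low choice noise and known leakage."""
    params = ModelParams(
        alpha=0.12, delta=0.03, tau=0.005, lambda_self=0.4, lambda_other=-0.2
    )
    traj = simulate_trajectory(default_sequence, params)
    responses = simulate_responses(traj, default_sequence, params, seed=99)
    return default_sequence, params, traj, responses


def random_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        alpha=rng.uniform(0.01, 0.99),
        delta=rng.uniform(0.0, 0.9),
        tau=rng.uniform(0.001, 0.08),
        lambda_self=rng.uniform(-1.0, 1.0),
        lambda_other=rng.uniform(-1.0, 1.0),
    )
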