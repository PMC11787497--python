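import numpy as np
import pandas as pd
import pytest

from tvareport import (
    DesignSpec,
    DurationCounts,
    PsychometricParams,
    evaluate_psychometric,
    generate_observers,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def observers9():
    """Nine simulated observers at the study's parameter scale."""
    return generate_observers(9, seed=11)


@pytest.fixture(scope="session")
def exp1_trials(observers9):
    """One dual-report session at the study's cell size (25 trials/cell)."""
    design = DesignSpec(trials_per_cell=25, mode="dual_report", seed=11)
    return simulate_experiment(observers9, design)


@pytest.fixture(scope="session")
def exp2_trials(observers9):
    """One blocked session per feature at the study's cell size (50 trials)."""
    frames = [
        simulate_experiment(observers9, DesignSpec(trials_per_cell=50, mode=m, seed=11))
        for m in ("blocked_location", "blocked_identity")
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def example_params():
    return PsychometricParams(t0_s=0.020, v_per_s=20.0, chance=1.0 / 12.0)


@pytest.fixture
def noisy_counts():
    """Binomially noisy per-duration counts from known parameters."""
    rng = np.random.default_rng(5)
    params = PsychometricParams(t0_s=0.025, v_per_s=22.0)
    durations = np.array([12, 24, 35, 47, 59, 71, 82, 106, 129, 176, 224]) / 1000.0
    n = 200
    return [
        DurationCounts(t, n, int(rng.binomial(n, evaluate_psychometric(params, t))))
        for t in durations
    ], params
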