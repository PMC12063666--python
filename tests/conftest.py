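import numpy as np
import pytest

from sarcokit.feedback import ModelParams, time_to_converge
from dataclasses import replace


def random_valid_params(rng: np.random.Generator, converged: bool = True) -> ModelParams:
    """A random parameter set inside the model's valid region.

    Valid region: L_I_min > 0, initial wall condition satisfied, and both
    initial lengths at or below their fixed-point values (the dynamics
    have no shrink terms, so convergence to the closed forms is only
    guaranteed from below).
    """
    L_I_max = rng.uniform(0.5, 3.0)
    tm_over_k = rng.uniform(0.1, 0.9) * L_I_max
    alpha = rng.uniform(0.1, 2.0)
    L_actin_0 = rng.uniform(0.0, L_I_max + alpha)
    L_A_0 = rng.uniform(max(0.0, L_actin_0 - L_I_max), alpha + tm_over_k)
    p = ModelParams(
        L_I_max=L_I_max,
        T_motor=tm_over_k,
        K_titin=1.0,
        alpha=alpha,
        T_c=rng.uniform(0.2, 2.0),
        T_r=rng.uniform(0.2, 2.0),
        v_actin_r=rng.uniform(0.01, 0.5),
        v_A_r=rng.uniform(0.01, 0.5),
        v_actin_c=rng.uniform(0.0, 0.2),
        L_actin_0=L_actin_0,
        L_A_0=L_A_0,
        total_time=1.0,
    )
    if converged:
        p = replace(p, total_time=time_to_converge(p))
    return p


@pytest.fixture(scope="session")
def converged_random_trajectories():
    """100 random valid parameter sets simulated to convergence (shared
    across the tests that check fixed points and invariants)."""
    from sarcokit.feedback import simulate

    rng = np.random.default_rng(20240917)
    runs = []
    for _ in range(100):
        p = random_valid_params(rng)
        runs.append((p, simulate(p)))
    return runs
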