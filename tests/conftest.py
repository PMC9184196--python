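import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from fhnsync import VARIANTS, Trajectory, default_t_end, reference_scenario, run_simulation

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None,
                          database=None)
settings.load_profile("ci")

#: Seed used for every stochastic benchmark run in the suite.
SUITE_SEED = 1


@pytest.fixture(scope="session")
def bench_runs():
    """Controlled and uncontrolled benchmark runs for all four variants.

    Computed once per session (the expensive part of the suite); keys are
    ``(variant, controlled)``.
    """
    runs = {}
    for variant in VARIANTS:
        cfg, sched = reference_scenario(variant)
        t_end = default_t_end(variant)
        runs[variant, True] = run_simulation(cfg, sched, t_end, seed=SUITE_SEED)
        unc = dataclasses.replace(sched, law="none")
        runs[variant, False] = run_simulation(cfg, unc, t_end, seed=SUITE_SEED)
    return runs


def synthetic_trajectory(errors: np.ndarray, dt: float) -> Trajectory:
    """A trajectory carrying prescribed error series (states zeroed).

    For metric/diagnostic tests that only look at ``times``/``errors``.
    """
    cfg, sched = reference_scenario("nondelayed_nonnoisy")
    T = errors.shape[0]
    n = cfg.n
    assert errors.shape[1] == 2 * n
    zeros = np.zeros((T, 2 * n))
    return Trajectory(
        times=np.arange(T) * dt,
        drive=zeros.copy(),
        slave=zeros.copy(),
        control=np.zeros((T, n)),
        errors=errors,
        controller_active=np.zeros(T, dtype=bool),
        dt=dt,
        method="rk4",
        seed=None,
        cfg=cfg,
        sched=sched,
    )
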