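"""Common additive membrane noise and what it does to synchronization.

The noisy variants inject the *same* Gaussian realization (intensity D,
increments of variance 2 D dt) into the drive and slave membranes, so the
noise cancels exactly in the drive-slave difference.  Strikingly, at the
default D = 0.01 the common noise alone synchronizes the two networks:
the uncontrolled error collapses to zero without any controller — a
noise-induced synchronization effect that removes the desynchronized
baseline the non-noisy scenario shows.
"""

import dataclasses

import numpy as np

from fhnsync import reference_scenario, run_simulation, sync_error_norm

cfg, sched = reference_scenario("nondelayed_noisy")
unc = dataclasses.replace(sched, law="none")

for D in (0.0, 0.001, 0.01):
    cfg_d = dataclasses.replace(cfg, noise=dataclasses.replace(cfg.noise, D=D))
    traj = run_simulation(cfg_d, unc, t_end=300.0, seed=1)
    m = sync_error_norm(traj, "max")
    k = np.searchsorted(traj.times, 150.0)
    print(f"D = {D:<6} uncontrolled peak error on (150, 300]: {m[k:].max():.3e}")
print("(with D = 0 the chaotic dynamics amplify the 1e-3 perturbation;\n"
      " common noise of modest intensity synchronizes the networks by itself)")
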