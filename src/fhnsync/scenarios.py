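"""The bundled five-neuron benchmark scenarios and YAML configuration I/O.

``reference_scenario`` builds the four drive/slave experiments used
throughout the test-suite and the CLI: five FHN neurons per network with
slightly heterogeneous parameters, common EES at ``A=0.1, f=0.129``, small
sinusoidal ionic disturbances, the fixed five-neuron gap-junction matrix,
and the controller switched on at ``t=150`` (non-delayed variants) or
``t=110`` (delayed variants).

Where the benchmark leaves a quantity open the module supplies a declared
default: gap-junction delays ``tau1=0.4, tau2=0.2``, noise intensity
``D=0.01``, and a ``1e-3`` additive perturbation of the slave membrane
initial conditions (the printed drive and slave initial conditions are
identical, which would make the uncontrolled non-delayed error identically
zero).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .coupling import CouplingMatrix, reference_coupling
from .model import (
    ControllerSchedule,
    DelayPair,
    EESDrive,
    FHNNeuronParams,
    IonicDisturbance,
    NetworkConfig,
    NoiseSpec,
    VARIANTS,
    variant_is_delayed,
    variant_is_noisy,
)

#: Default integration step.
DEFAULT_DT = 0.005

#: Declared defaults for quantities the benchmark leaves open.
DEFAULT_TAU1 = 0.4
DEFAULT_TAU2 = 0.2
DEFAULT_NOISE_D = 0.01
DEFAULT_PERTURBATION = 1e-3

_R = (10.0, 10.2, 10.4, 10.6, 10.8)
_B = (1.0, 1.001, 1.002, 1.003, 1.004)
_C = (0.001, 0.002, 0.003, 0.004, 0.005)
_D_AMP = (0.001, 0.002, 0.003, 0.004, 0.005)
_D_RATE = 0.2
_A = 0.1
_F = 0.129
# Initial conditions, identical for drive and slave:
# membranes x_i1(0), then recoveries x_i2(0).
_IC = (0.0, 0.05, 0.05, 0.0, 0.05, 0.1, 0.2, 0.2, 0.1, 0.2)
_T_ON_NONDELAYED = 150.0
_T_ON_DELAYED = 110.0


def default_t_end(variant: str) -> float:
    """Default horizon: 300 for the non-delayed, 250 for the delayed variants."""
    return 250.0 if variant_is_delayed(variant) else 300.0


def reference_scenario(
    variant: str,
    slave_ic_perturbation: float = DEFAULT_PERTURBATION,
    tau1: float = DEFAULT_TAU1,
    tau2: float = DEFAULT_TAU2,
    noise_D: float = DEFAULT_NOISE_D,
    noise_seed: int = 0,
):
    """Build the five-neuron benchmark configuration for one variant.

    Returns ``(NetworkConfig, ControllerSchedule)``.  The schedule selects
    the control law matching the variant class, activated at the benchmark
    time (150 non-delayed, 110 delayed).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    delayed = variant_is_delayed(variant)
    noisy = variant_is_noisy(variant)
    cfg = NetworkConfig(
        n=5,
        params=tuple(FHNNeuronParams(r, b, c) for r, b, c in zip(_R, _B, _C)),
        ees=EESDrive(A=_A, f=_F),
        disturbances=tuple(IonicDisturbance(a, _D_RATE) for a in _D_AMP),
        coupling=reference_coupling(),
        delays=DelayPair(tau1, tau2) if delayed else DelayPair(0.0, 0.0),
        noise=NoiseSpec(D=noise_D, seed=noise_seed) if noisy else None,
        drive_ic=np.array(_IC),
        slave_ic=np.array(_IC),
        slave_ic_perturbation=slave_ic_perturbation,
        variant=variant,
    )
    sched = ControllerSchedule(
        law="delayed" if delayed else "nondelayed",
        t_on=_T_ON_DELAYED if delayed else _T_ON_NONDELAYED,
    )
    return cfg, sched


# ---------------------------------------------------------------------------
# Serialization


def config_to_dict(cfg: NetworkConfig, sched: ControllerSchedule) -> dict:
    """Plain-types mapping of a configuration (YAML/JSON friendly)."""
    d = {
        "variant": cfg.variant,
        "n": cfg.n,
        "r": [p.r for p in cfg.params],
        "b": [p.b for p in cfg.params],
        "c": [p.c for p in cfg.params],
        "ees_A": cfg.ees.A,
        "ees_f": cfg.ees.f,
        "disturbance_amplitude": [di.amplitude for di in cfg.disturbances],
        "disturbance_rate": [di.rate for di in cfg.disturbances],
        "coupling": [[float(v) for v in row] for row in cfg.coupling.G],
        "tau1": cfg.delays.tau1,
        "tau2": cfg.delays.tau2,
        "drive_ic": [float(v) for v in cfg.drive_ic],
        "slave_ic": [float(v) for v in cfg.slave_ic],
        "slave_ic_perturbation": cfg.slave_ic_perturbation,
        "controller_law": sched.law,
        "controller_t_on": sched.t_on,
        "controller_gain_columns": list(sched.gain_columns),
    }
    if cfg.noise is not None:
        d["noise_D"] = cfg.noise.D
        d["noise_seed"] = cfg.noise.seed
        d["noise_common"] = cfg.noise.common
    return d


def config_from_dict(d: dict):
    """Inverse of :func:`config_to_dict`."""
    n = int(d["n"])
    noise = None
    if "noise_D" in d:
        noise = NoiseSpec(
            D=float(d["noise_D"]),
            seed=int(d.get("noise_seed", 0)),
            common=bool(d.get("noise_common", True)),
        )
    cfg = NetworkConfig(
        n=n,
        params=tuple(
            FHNNeuronParams(r, b, c) for r, b, c in zip(d["r"], d["b"], d["c"])
        ),
        ees=EESDrive(A=float(d["ees_A"]), f=float(d["ees_f"])),
        disturbances=tuple(
            IonicDisturbance(a, r)
            for a, r in zip(d["disturbance_amplitude"], d["disturbance_rate"])
        ),
        coupling=CouplingMatrix(np.array(d["coupling"], dtype=float)),
        delays=DelayPair(float(d["tau1"]), float(d["tau2"])),
        noise=noise,
        drive_ic=np.array(d["drive_ic"], dtype=float),
        slave_ic=np.array(d["slave_ic"], dtype=float),
        slave_ic_perturbation=float(d["slave_ic_perturbation"]),
        variant=d["variant"],
    )
    sched = ControllerSchedule(
        law=d["controller_law"],
        t_on=float(d["controller_t_on"]),
        gain_columns=tuple(d["controller_gain_columns"]),
    )
    return cfg, sched


def save_config(cfg: NetworkConfig, sched: ControllerSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg, sched), fh, sort_keys=True)


def load_config(path):
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def packaged_config(variant: str):
    """Load one of the four benchmark scenarios shipped with the package."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    ref = resources.files("fhnsync") / "data" / f"{variant}.yaml"
    return config_from_dict(yaml.safe_load(ref.read_text()))
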